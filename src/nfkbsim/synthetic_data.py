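"""Pseudo-experimental replicate datasets with the assay structure of the
population-level measurements: ELISA time courses for NF-κB p65 DNA binding,
IKK kinase activity, total and Ser32-phospho IκBα, plus qPCR Ct tables for
IκBα/A20 transcripts with GAPDH as internal reference.

Replicates are the model observable at each sampled time multiplied by
lognormal noise (the assays report mean ± SD of strictly positive
normalized quantities, for which multiplicative error is the natural
family; this is a stated assumption, recorded in each dataset).  Both cell
types are normalized by the *control* dataset's mean at the assay's
reference time point, mirroring how the measured curves are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readouts import evaluate_observable
from .simulate import Trajectory

__all__ = [
    "AssaySpec",
    "SyntheticAssayDataset",
    "DEFAULT_ASSAYS",
    "generate_assay",
    "generate_qpcr",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class AssaySpec:
    """Sampling design of one assay."""

    assay: str
    observable: str
    times: tuple[float, ...]
    n: int
    reference_time: float
    cv: float = 0.15

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")
        if self.reference_time not in self.times:
            raise ValueError("reference time must be one of the sampled times")


#: Sampling times and replicate counts of the measured time courses.
DEFAULT_ASSAYS: dict[str, AssaySpec] = {
    "p65-ELISA": AssaySpec("p65-ELISA", "nuclear_nfkb",
                           (0, 15, 20, 30, 105, 150), n=6, reference_time=20),
    "IKK-ELISA": AssaySpec("IKK-ELISA", "ikk_active",
                           (0, 2.5, 5, 10, 20), n=6, reference_time=5),
    "totalIkBa-ELISA": AssaySpec("totalIkBa-ELISA", "total_ikba",
                                 (0, 5, 20, 60, 90), n=9, reference_time=0),
    "pIkBa-ELISA": AssaySpec("pIkBa-ELISA", "phospho_ikba",
                             (0, 5, 20, 60, 90), n=9, reference_time=5),
}


@dataclass
class SyntheticAssayDataset:
    """Replicate normalized measurements for one assay and one cell type."""

    assay: str
    cell_type: str
    times: np.ndarray
    values: np.ndarray  # shape (n_replicates, n_times)
    cv: float
    seed: int
    normalization: str
    noise_model: str = "multiplicative lognormal"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times.size:
            raise ValueError("values must have shape (n_replicates, n_times)")
        if np.any(self.values < 0):
            raise ValueError("replicate values must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: (assay, cell_type, time_min, replicate, value)."""
        n, m = self.values.shape
        return pd.DataFrame({
            "assay": self.assay,
            "cell_type": self.cell_type,
            "time_min": np.tile(self.times, n),
            "replicate": np.repeat(np.arange(n), m),
            "value": self.values.ravel(),
        })


def _sample_at(traj: Trajectory, obs: str, times) -> np.ndarray:
    return np.array([evaluate_observable(traj.at_time(t), obs) for t in times])


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, shape))


def generate_assay(
    traj_control: Trajectory,
    traj_scenario: Trajectory,
    spec: AssaySpec,
    seed: int,
) -> tuple[SyntheticAssayDataset, SyntheticAssayDataset]:
    """Generate paired control/scenario replicate datasets for one assay.

    Replicates are ``model value × exp(N(0, σ²))`` with σ² = ln(1 + CV²);
    both datasets are then divided by the control replicates' mean at the
    assay's reference time point.  With CV = 0 the replicates equal the
    normalized model values exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    raw = {}
    for cell, traj in (("control", traj_control), ("scenario", traj_scenario)):
        mu = _sample_at(traj, spec.observable, spec.times)
        noise = _lognormal_factors(rng, spec.cv, (spec.n, len(spec.times)))
        raw[cell] = mu[None, :] * noise
    ref_col = spec.times.index(spec.reference_time)
    if spec.cv == 0:
        # replicates are identical; take the value itself so the noiseless
        # pipeline is bit-exact (np.mean of n equal values can round)
        ref = raw["control"][0, ref_col]
    else:
        ref = raw["control"][:, ref_col].mean()
    if ref == 0:
        raise ZeroDivisionError(
            f"control mean at reference time {spec.reference_time} min is zero"
        )
    norm_note = (f"divided by control mean at t = {spec.reference_time} min")
    for cell in ("control", "scenario"):
        out.append(SyntheticAssayDataset(
            assay=spec.assay, cell_type=cell, times=np.array(spec.times),
            values=raw[cell] / ref, cv=spec.cv, seed=seed,
            normalization=norm_note,
        ))
    return out[0], out[1]


def generate_qpcr(
    traj: Trajectory,
    times=(0, 30, 60, 120),
    n: int = 3,
    seed: int = 0,
    ct_sd: float = 0.25,
    targets: tuple[str, ...] = ("ikba_mrna", "a20_mrna"),
    reference_gene: str = "GAPDH",
    target_offset: float = 22.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for transcript observables plus the reference gene.

    Target Ct = offset − log2(transcript level) + noise, so doubling the
    transcript lowers Ct by one cycle; the reference gene's Ct is
    independent of the stimulus.  Levels are expressed relative to the
    trajectory's t = 0 transcript level before taking logs, which fixes the
    offset's meaning (Ct of the unstimulated sample).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in targets:
        level = _sample_at(traj, gene, times)
        if np.any(level <= 0):
            raise ValueError(f"nonpositive transcript level for {gene}")
        rel = level / level[0]
        for j, t in enumerate(times):
            ct = target_offset - np.log2(rel[j]) + rng.normal(0, ct_sd, n)
            rows += [{"gene": gene, "time_min": float(t), "replicate": r,
                      "ct": float(ct[r])} for r in range(n)]
    for t in times:
        ct = reference_ct + rng.normal(0, ct_sd, n)
        rows += [{"gene": reference_gene, "time_min": float(t), "replicate": r,
                  "ct": float(ct[r])} for r in range(n)]
    return pd.DataFrame(rows)


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    reference_time: float = 0.0,
) -> pd.DataFrame:
    """Relative quantification: fold change = 2^(−ΔΔCt).

    ΔCt normalizes each replicate's target Ct to the reference gene at the
    same time point (replicates paired by index); ΔΔCt subtracts the mean
    ΔCt of the reference time point.
    """
    tgt = ct_table[ct_table["gene"] == target_gene]
    ref = ct_table[ct_table["gene"] == reference_gene]
    if tgt.empty or ref.empty:
        raise ValueError("target or reference gene missing from the Ct table")
    merged = tgt.merge(ref, on=["time_min", "replicate"], suffixes=("_tgt", "_ref"))
    merged["dct"] = merged["ct_tgt"] - merged["ct_ref"]
    base = merged.loc[merged["time_min"] == reference_time, "dct"].mean()
    if np.isnan(base):
        raise ValueError(f"no rows at reference time {reference_time}")
    merged["ddct"] = merged["dct"] - base
    merged["fold_change"] = 2.0 ** (-merged["ddct"])
    return merged[["time_min", "replicate", "dct", "ddct", "fold_change"]]
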