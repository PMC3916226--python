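"""Derived observables and the normalizations applied to reported curves.

The single place where model species are mapped onto assay readouts:
"NF-κB activity" (DNA-binding ELISA) is the free nuclear NF-κB
concentration — complexed nuclear NF-κB is inhibited and does not bind DNA;
"IKK activity" is the active IKK form; "total IκBα" sums every species
containing an IκBα molecule over both compartments; "phospho-IκBα" sums the
tagged intermediates (all of which carry the Ser32 mark en route to the
proteasome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import IKBA_SPECIES, SPECIES_INDEX, TAGGED_IKBA_SPECIES
from .simulate import Trajectory

__all__ = [
    "OBSERVABLES",
    "ObservableSeries",
    "evaluate_observable",
    "observable",
    "peak",
    "steady_state_ratio",
    "normalize",
    "denormalize",
    "tagged_fraction",
]


def _sum_species(y: np.ndarray, names) -> np.ndarray:
    idx = [SPECIES_INDEX[n] for n in names]
    return y[..., idx].sum(axis=-1)


#: Observable name -> function of a state matrix (rows = time points).
OBSERVABLES = {
    "nuclear_nfkb": lambda y: y[..., SPECIES_INDEX["NFkBn"]],
    "ikk_active": lambda y: y[..., SPECIES_INDEX["IKKa"]],
    "total_ikba": lambda y: _sum_species(y, IKBA_SPECIES),
    "phospho_ikba": lambda y: _sum_species(y, TAGGED_IKBA_SPECIES),
    "free_ikba": lambda y: y[..., SPECIES_INDEX["IkBa"]],
    "ikba_mrna": lambda y: y[..., SPECIES_INDEX["IkBa_mRNA"]],
    "a20_mrna": lambda y: y[..., SPECIES_INDEX["A20_mRNA"]],
    "a20": lambda y: y[..., SPECIES_INDEX["A20"]],
}


@dataclass
class ObservableSeries:
    """One derived time series plus the normalization that produced it."""

    name: str
    t: np.ndarray
    values: np.ndarray
    #: (scale, offset): stored affine coefficients; raw = scale * v + offset.
    normalization: tuple | None = None
    mode: str | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("time grid and values must have identical shape")
        if self.t.size == 0:
            raise ValueError("empty series")


def evaluate_observable(state: np.ndarray, name: str):
    """Evaluate an observable on a single state vector or a state matrix."""
    try:
        fn = OBSERVABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown observable {name!r}; valid: {sorted(OBSERVABLES)}"
        ) from None
    return fn(np.asarray(state, dtype=float))


def observable(traj: Trajectory, name: str) -> ObservableSeries:
    return ObservableSeries(name=name, t=traj.t, values=evaluate_observable(traj.y, name))


def peak(series: ObservableSeries) -> tuple[float, float]:
    """Global maximum on the grid; ties broken by the earliest time."""
    i = int(np.argmax(series.values))  # argmax returns the first maximum
    return float(series.values[i]), float(series.t[i])


def steady_state_ratio(scenario_eq: np.ndarray, nominal_eq: np.ndarray,
                       observable_name: str) -> float:
    """Scenario/nominal ratio of an observable at equilibrium.

    Returns NaN (with no exception) when the nominal value is numerically
    zero, since the ratio is then undefined.
    """
    num = float(evaluate_observable(scenario_eq, observable_name))
    den = float(evaluate_observable(nominal_eq, observable_name))
    if abs(den) < 1e-300:
        return float("nan")
    return num / den


def normalize(series: ObservableSeries, mode: str,
              reference_time: float | None = None) -> ObservableSeries:
    """Apply one of the normalization rules used for reported curves.

    Modes
    -----
    ``reference_timepoint``
        Divide by the value at ``reference_time`` (that point maps to 1),
        the rule used for the ELISA time courses.
    ``basal_is_10pct_of_max``
        Affine map sending (basal, max) to (0.10, 1.0), the rescaling used
        when overlaying data on simulated IKK/NF-κB curves.
    ``fold_over_initial``
        Divide by the t = 0 value, the rule used for transcript levels.
    """
    v = series.values
    if mode == "reference_timepoint":
        if reference_time is None:
            raise ValueError("reference_timepoint mode needs reference_time")
        hits = np.flatnonzero(np.isclose(series.t, reference_time, rtol=0, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"reference time {reference_time} not on the grid")
        ref = v[hits[0]]
        if ref == 0:
            raise ZeroDivisionError("reference value is zero")
        scale, offset = ref, 0.0
    elif mode == "basal_is_10pct_of_max":
        basal, vmax = v[0], v.max()
        if vmax == basal:
            raise ZeroDivisionError("flat series: basal equals maximum")
        # solve v = scale * out + offset with (basal -> 0.10, max -> 1.0)
        scale = (vmax - basal) / 0.9
        offset = basal - 0.10 * scale
    elif mode == "fold_over_initial":
        if v[0] == 0:
            raise ZeroDivisionError("initial value is zero")
        scale, offset = v[0], 0.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(series, values=(v - offset) / scale,
                   normalization=(float(scale), float(offset)), mode=mode)


def denormalize(series: ObservableSeries) -> ObservableSeries:
    """Invert a stored normalization, recovering the raw series."""
    if series.normalization is None:
        raise ValueError("series carries no normalization to invert")
    scale, offset = series.normalization
    return replace(series, values=series.values * scale + offset,
                   normalization=None, mode=None)


def tagged_fraction(traj: Trajectory, time: float) -> float:
    """Fraction of total IκBα in a phosphorylated or ubiquitinated state at ``time``.

    NaN when total IκBα is numerically zero.
    """
    state = traj.at_time(time)
    total = float(evaluate_observable(state, "total_ikba"))
    if total < 1e-300:
        return float("nan")
    return float(evaluate_observable(state, "phospho_ikba")) / total
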