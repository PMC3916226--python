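"""Core NF-κB signaling network: species, rate constants, and ODE right-hand side.

The model describes TNFα-induced activation of NF-κB in microglia through the
canonical pathway: a three-state IKK module (neutral → active → inactivated →
neutral), IKK-catalyzed phosphorylation of IκBα followed by E3-ligase
recruitment, poly-ubiquitination and proteasomal degradation, release and
nuclear translocation of NF-κB, and two NF-κB-induced negative feedbacks —
resynthesis of IκBα and induction of A20, which accelerates inactivation of
active IKK.  Two structural features distinguish it from the classical
Lipniacki-family core: phosphorylated/ubiquitinated IκBα intermediates are
also degraded constitutively, and the cytoplasmic IκBα:NF-κB complex may be
imported into the nucleus.

Units: concentrations in µM, time in minutes.  TNFα stimulus is a binary
input (0 = absent, 1 = present); basal IKK activation in the absence of
stimulus is zero.  Total NF-κB and total IKK are strictly conserved — the
network contains no synthesis or degradation of either protein backbone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "SPECIES_INDEX",
    "NFKB_SPECIES",
    "IKK_SPECIES",
    "IKBA_SPECIES",
    "TAGGED_IKBA_SPECIES",
    "PARAMETER_NAMES",
    "ParameterSet",
    "InitialPools",
    "nominal_parameters",
    "nominal_pools",
    "parameter_manifest",
    "initial_state",
    "rhs",
    "make_rhs",
    "nfkb_total",
    "ikk_total",
]

#: Fixed state-vector ordering.  ``p``/``pu``/``u`` prefixes mark the
#: phosphorylated, E3-engaged and poly-ubiquitinated IκBα intermediates;
#: the ``NFkB`` suffix marks NF-κB-bound forms; trailing ``n`` marks
#: nuclear pools.
SPECIES: tuple[str, ...] = (
    "IKKn", "IKKa", "IKKi",
    "IkBa", "pIkBa", "puIkBa", "uIkBa",
    "IkBaNFkB", "pIkBaNFkB", "puIkBaNFkB", "uIkBaNFkB",
    "NFkB", "NFkBn", "IkBan", "IkBaNFkBn",
    "IkBa_mRNA", "A20_mRNA", "A20",
)
N_SPECIES = len(SPECIES)
SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Species containing the NF-κB protein backbone (conserved).
NFKB_SPECIES = ("IkBaNFkB", "pIkBaNFkB", "puIkBaNFkB", "uIkBaNFkB",
                "NFkB", "NFkBn", "IkBaNFkBn")
#: Species containing the IKK protein backbone (conserved).
IKK_SPECIES = ("IKKn", "IKKa", "IKKi")
#: Every species containing an IκBα protein molecule.
IKBA_SPECIES = ("IkBa", "pIkBa", "puIkBa", "uIkBa",
                "IkBaNFkB", "pIkBaNFkB", "puIkBaNFkB", "uIkBaNFkB",
                "IkBan", "IkBaNFkBn")
#: Phospho-/ubiquitin-tagged IκBα intermediates en route to the proteasome.
TAGGED_IKBA_SPECIES = ("pIkBa", "puIkBa", "uIkBa",
                       "pIkBaNFkB", "puIkBaNFkB", "uIkBaNFkB")

PARAMETER_NAMES: tuple[str, ...] = (
    # IKK module
    "ka", "kp", "ki", "kiA20",
    # IκBα / NF-κB binding
    "a1", "d1a",
    # IκBα phosphorylation → ubiquitination → proteasomal degradation
    "kc2a", "kc1a", "kua1", "kuc1", "kupd", "kdpi",
    # constitutive IκBα turnover
    "c5a", "c6a",
    # nuclear transport
    "i1", "i1a", "e1a", "e2a", "i2a",
    # IκBα gene: transcription, mRNA decay, translation
    "c1a", "c3a", "c2a",
    # A20 gene: transcription, mRNA decay, translation, protein decay
    "c1", "c3", "c2", "c5",
    # Hill activation constant of NF-κB-driven transcription
    "Ka",
)

_PARAM_SET = frozenset(PARAMETER_NAMES)


class UnknownParameterError(KeyError):
    """Raised when a rate-constant name is not part of the model."""


def _check_name(name: str) -> None:
    if name not in _PARAM_SET:
        raise UnknownParameterError(
            f"unknown rate constant {name!r}; valid names: "
            + ", ".join(PARAMETER_NAMES)
        )


class ParameterSet(Mapping[str, float]):
    """Immutable named collection of nonnegative rate constants.

    Behaves as a mapping and additionally exposes each rate as an
    attribute (``params.ka``).  Serialises losslessly to/from JSON.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        missing = _PARAM_SET - set(values)
        if missing:
            raise ValueError(f"missing rate constants: {sorted(missing)}")
        for name in values:
            _check_name(name)
        vals = {}
        for name in PARAMETER_NAMES:
            v = float(values[name])
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name!r} must be finite and >= 0, got {v}")
            vals[name] = v
        object.__setattr__(self, "_values", vals)

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("ParameterSet is immutable")

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        _check_name(name)
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAMETER_NAMES)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __repr__(self) -> str:
        return f"ParameterSet({self._values!r})"

    def with_factors(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with the named rates multiplied by the given factors.

        Untouched entries are bit-identical to the originals.
        """
        for name in factors:
            _check_name(name)
        vals = dict(self._values)
        for name, f in factors.items():
            vals[name] = vals[name] * float(f)
        return ParameterSet(vals)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_json(self) -> str:
        return json.dumps(self._values, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls(json.loads(text))

    def digest(self) -> str:
        """Content hash used to tag trajectories with their parameter provenance."""
        payload = json.dumps(self._values, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class InitialPools:
    """Conserved protein totals provided as initial conditions.

    The whole NF-κB pool starts as cytoplasmic IκBα:NF-κB complex and the
    whole IKK pool as neutral IKK; every other species starts at zero and is
    filled in by pre-stimulus equilibration.
    """

    nfkb_total: float
    ikk_total: float

    def __post_init__(self):
        for field in ("nfkb_total", "ikk_total"):
            v = getattr(self, field)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{field} must be finite and >= 0, got {v}")

    _POOL_NAMES = ("NFkB_pool", "IKKn_pool")

    def with_factors(self, factors: Mapping[str, float]) -> "InitialPools":
        """Multiplicative scaling by pool name (``NFkB_pool``, ``IKKn_pool``)."""
        unknown = set(factors) - set(self._POOL_NAMES)
        if unknown:
            raise UnknownParameterError(
                f"unknown pool name(s) {sorted(unknown)}; valid names: "
                + ", ".join(self._POOL_NAMES)
            )
        nfkb = self.nfkb_total * float(factors.get("NFkB_pool", 1.0))
        ikk = self.ikk_total * float(factors.get("IKKn_pool", 1.0))
        return InitialPools(nfkb, ikk)

    def to_dict(self) -> dict[str, float]:
        return {"nfkb_total": self.nfkb_total, "ikk_total": self.ikk_total}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "InitialPools":
        return cls(float(d["nfkb_total"]), float(d["ikk_total"]))


def parameter_manifest() -> dict:
    """Full parameter manifest (values, units, provenance notes)."""
    with resources.files("nfkbsim.data").joinpath("parameters.json").open() as fh:
        return json.load(fh)


def nominal_parameters() -> ParameterSet:
    """Nominal rate constants of the control-cell model."""
    manifest = parameter_manifest()
    return ParameterSet({k: v["value"] for k, v in manifest["rates"].items()})


def nominal_pools() -> InitialPools:
    manifest = parameter_manifest()
    return InitialPools(
        nfkb_total=manifest["pools"]["NFkB_pool"]["value"],
        ikk_total=manifest["pools"]["IKKn_pool"]["value"],
    )


def initial_state(pools: InitialPools) -> np.ndarray:
    """Pre-equilibration state: all NF-κB complexed in the cytoplasm, all IKK neutral."""
    x = np.zeros(N_SPECIES)
    x[SPECIES_INDEX["IkBaNFkB"]] = pools.nfkb_total
    x[SPECIES_INDEX["IKKn"]] = pools.ikk_total
    return x


def _rhs_raw(x: np.ndarray, p: ParameterSet, tnf: float) -> np.ndarray:
    (IKKn, IKKa, IKKi,
     IkBa, pIkBa, puIkBa, uIkBa,
     C, pC, puC, uC,
     NFkB, NFkBn, IkBan, Cn,
     mI, mA, A20) = x

    d = np.empty(N_SPECIES)

    # IKK module: n -> a (TNF-gated), a -> i (spontaneous + A20-dependent), i -> n
    act = p.ka * tnf * IKKn
    inact = (p.ki + p.kiA20 * A20) * IKKa
    rec = p.kp * IKKi
    d[0] = -act + rec
    d[1] = act - inact
    d[2] = inact - rec

    # IκBα / NF-κB association-dissociation, both compartments
    bind_c = p.a1 * IkBa * NFkB - p.d1a * C
    bind_n = p.a1 * IkBan * NFkBn - p.d1a * Cn

    # IKK-catalyzed phosphorylation (complexed faster than free IκBα)
    ph_f = p.kc1a * IKKa * IkBa
    ph_c = p.kc2a * IKKa * C

    # free cytoplasmic IκBα
    d[3] = (p.c2a * mI - bind_c - ph_f - p.c5a * IkBa
            - p.i1a * IkBa + p.e1a * IkBan)
    # free tagged chain: phospho -> E3-engaged -> poly-Ub -> proteasome,
    # each intermediate also degraded constitutively (kdpi)
    d[4] = ph_f - (p.kua1 + p.kdpi) * pIkBa
    d[5] = p.kua1 * pIkBa - (p.kuc1 + p.kdpi) * puIkBa
    d[6] = p.kuc1 * puIkBa - (p.kupd + p.kdpi) * uIkBa

    # cytoplasmic complex (nuclear import of the complex allowed, rate i2a)
    d[7] = bind_c - ph_c - p.c6a * C - p.i2a * C + p.e2a * Cn
    # complexed tagged chain; degradation of the IκBα moiety frees NF-κB
    d[8] = ph_c - (p.kua1 + p.kdpi) * pC
    d[9] = p.kua1 * pC - (p.kuc1 + p.kdpi) * puC
    d[10] = p.kuc1 * puC - (p.kupd + p.kdpi) * uC
    released = p.kupd * uC + p.kdpi * (pC + puC + uC) + p.c6a * C

    # free NF-κB, cytoplasmic then nuclear
    d[11] = -bind_c + released - p.i1 * NFkB
    d[12] = p.i1 * NFkB - bind_n + p.c6a * Cn

    # nuclear free IκBα and nuclear complex
    d[13] = -bind_n + p.i1a * IkBa - p.e1a * IkBan - p.c5a * IkBan
    d[14] = bind_n - p.e2a * Cn + p.i2a * C - p.c6a * Cn

    # NF-κB-induced transcription with Hill-2 activation; identical control
    # of the IκBα and A20 genes, independent decay and translation
    hill = NFkBn * NFkBn / (p.Ka * p.Ka + NFkBn * NFkBn)
    d[15] = p.c1a * hill - p.c3a * mI
    d[16] = p.c1 * hill - p.c3 * mA
    d[17] = p.c2 * mA - p.c5 * A20
    return d


def rhs(state: np.ndarray, params: ParameterSet, stimulus_on: bool) -> np.ndarray:
    """Time derivative of every dynamic species.

    Parameters
    ----------
    state:
        Concentration vector ordered as :data:`SPECIES` (µM).
    params:
        Rate constants.
    stimulus_on:
        Whether TNFα is present.  With the stimulus off the TNF-dependent
        IKK activation flux is identically zero.

    Raises
    ------
    ValueError
        If the state is non-finite or negative.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        bad = [SPECIES[i] for i in np.flatnonzero(~np.isfinite(x))]
        raise ValueError(f"non-finite concentration(s) for {bad}")
    if np.any(x < 0):
        bad = [SPECIES[i] for i in np.flatnonzero(x < 0)]
        raise ValueError(f"negative concentration(s) for {bad}")
    return _rhs_raw(x, params, 1.0 if stimulus_on else 0.0)


def make_rhs(params: ParameterSet, stimulus_on: bool):
    """Unvalidated ``f(t, x)`` closure for use inside ODE integrators.

    Integrators probe trial states that may be transiently (and harmlessly)
    slightly negative, so the strict validation of :func:`rhs` is skipped.
    """
    tnf = 1.0 if stimulus_on else 0.0

    def f(t: float, x: np.ndarray) -> np.ndarray:
        return _rhs_raw(x, params, tnf)

    return f


def _group_total(state: np.ndarray, names: tuple[str, ...]) -> float | np.ndarray:
    idx = [SPECIES_INDEX[n] for n in names]
    arr = np.asarray(state, dtype=float)
    if arr.ndim == 1:
        return float(arr[idx].sum())
    return arr[..., idx].sum(axis=-1)


def nfkb_total(state: np.ndarray):
    """Total NF-κB protein (free, complexed, nuclear); conserved quantity."""
    return _group_total(state, NFKB_SPECIES)


def ikk_total(state: np.ndarray):
    """Total IKK protein over its three forms; conserved quantity."""
    return _group_total(state, IKK_SPECIES)
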