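"""Linear compartment model of cytosine methylation and active demethylation.

The model tracks six genomic nucleoside pools — 5-methyl-dC (``mdC``),
5-hydroxymethyl-dC (``hmdC``), 5-formyl-dC (``fdC``), 5-carboxy-dC
(``cadC``), 5-hydroxymethyl-dU (``hmdU``) and dU (``U``) — connected by ten
mass-action fluxes:

====  =======================================  ============================
flux  expression                               reaction
====  =======================================  ============================
f1    kDNMT1 * C * DNMT1                       dC -> mdC (maintenance methylation)
f2    sum_{i in s1} k1_i * mdC * TETi          mdC -> hmdC (TET oxidation 1)
f3    sum_{i in s2} k2_i * hmdC * TETi         hmdC -> fdC (TET oxidation 2)
f4    sum_{i in s3} k3_i * fdC * TETi          fdC -> cadC (TET oxidation 3)
f5    k4 * fdC                                 fdC -> dC (TDG-initiated repair)
f6    k5 * cadC                                cadC -> dC (TDG-initiated repair)
f7    kAID_hmdC * hmdC * AID                   hmdC -> hmdU (deamination)
f8    kSMUG * hmdU * SMUG1                     hmdU -> dC (SMUG1-initiated repair)
f9    kTDG * U * TDG                           dU -> dC (TDG-initiated repair)
f10   kAID_C * C * AID                         dC -> dU (deamination)
====  =======================================  ============================

Enzyme transcript levels stand in for enzyme activities, the unmodified-dC
pool ``C`` is an exogenous constant, and kinetics are linear in the state
(the system is assumed to operate in the linear part of any saturating
characteristic). Which TET paralogs participate in each of the three
oxidation reactions is given by a :class:`ModelStructure` (subsets s1, s2,
s3 of {TET1, TET2, TET3}); rate coefficients of excluded paralogs are
masked to zero.

The six ODEs are, in the fixed state ordering
``(mdC, hmdC, fdC, cadC, hmdU, U)``::

    d mdC/dt  = f1 - f2
    d hmdC/dt = f2 - f3 - f7
    d fdC/dt  = f3 - f4 - f5
    d cadC/dt = f4 - f6
    d hmdU/dt = f7 - f8
    d U/dt    = f10 - f9

The dU equation is written production-minus-removal like every other
compartment, so dU accumulates under AID action and decays under TDG
action; at steady state (f9 = f10) the sign convention is immaterial.

The system is linear with a lower-triangular Jacobian, so all eigenvalues
are real (the diagonal entries, each the negated total removal rate of one
species): for strictly positive rates the steady state is asymptotically
stable and relaxation is aperiodic. The steady state follows in closed
form by cascading the flux balances f1=f2, f2=f3+f7, f3=f4+f5, f4=f6,
f7=f8, f9=f10.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, NoFiniteSteadyStateError, ValidationError

__all__ = [
    "SPECIES",
    "TETS",
    "EnzymeProfile",
    "ModificationState",
    "ExogenousPool",
    "ModelStructure",
    "RateParameters",
    "FluxVector",
    "StabilityReport",
    "Trajectory",
    "compute_fluxes",
    "time_derivatives",
    "system_matrix",
    "check_stability",
    "steady_state",
    "simulate",
    "is_steady",
]

#: Canonical state ordering used everywhere, including file columns.
SPECIES = ("mdC", "hmdC", "fdC", "cadC", "hmdU", "U")

#: TET paralog ordering (index 0..2) used in masks and dot patterns.
TETS = ("TET1", "TET2", "TET3")


def _validate_nonnegative_finite(obj, fields: Iterable[str]) -> None:
    for name in fields:
        value = getattr(obj, name)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(
                f"{type(obj).__name__}.{name} must be a real number, got {value!r}"
            )
        if not math.isfinite(value):
            raise ValidationError(f"{type(obj).__name__}.{name} must be finite, got {value!r}")
        if value < 0:
            raise ValidationError(f"{type(obj).__name__}.{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class EnzymeProfile:
    """Relative transcript levels of the seven enzymes driving the fluxes.

    Levels are non-negative reals on a scale consistent across cell lines
    (e.g. RT-qPCR relative expression). A zero level is legal — reaction
    participation is controlled by the structure mask, not by enzyme
    abundance.
    """

    dnmt1: float
    tet1: float
    tet2: float
    tet3: float
    aid: float
    smug1: float
    tdg: float
    cell_line_id: str = ""

    _NUMERIC = ("dnmt1", "tet1", "tet2", "tet3", "aid", "smug1", "tdg")

    def __post_init__(self):
        for name in self._NUMERIC:
            object.__setattr__(self, name, float(getattr(self, name)))
        _validate_nonnegative_finite(self, self._NUMERIC)

    @property
    def tet_levels(self) -> np.ndarray:
        """Levels of (TET1, TET2, TET3) as an array."""
        return np.array([self.tet1, self.tet2, self.tet3])


@dataclass(frozen=True)
class ModificationState:
    """The six state variables: modified-cytidine/uridine levels.

    Ordering matches :data:`SPECIES`: (mdC, hmdC, fdC, cadC, hmdU, U).
    """

    mdC: float
    hmdC: float
    fdC: float
    cadC: float
    hmdU: float
    U: float

    def __post_init__(self):
        for name in SPECIES:
            object.__setattr__(self, name, float(getattr(self, name)))
        _validate_nonnegative_finite(self, SPECIES)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES])

    @classmethod
    def from_array(cls, values) -> "ModificationState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(SPECIES),):
            raise ValidationError(f"expected {len(SPECIES)} state values, got shape {values.shape}")
        return cls(*values)


@dataclass(frozen=True)
class ExogenousPool:
    """The unmodified-deoxycytidine pool, treated as a constant.

    The pool is exogenous: no dC balance equation is carried, and C can be
    absorbed into kDNMT1 and kAID_C without changing any observable.
    """

    C: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "C", float(self.C))
        if not math.isfinite(self.C) or self.C <= 0:
            raise ValidationError(f"ExogenousPool.C must be a finite positive real, got {self.C!r}")


def _coerce_subset(value) -> frozenset:
    if isinstance(value, str):
        value = (value,)
    subset = frozenset(value)
    unknown = subset - set(TETS)
    if unknown:
        raise ValidationError(f"unknown TET name(s) {sorted(unknown)}; valid names are {TETS}")
    if not subset:
        raise ValidationError("each oxidation reaction needs a non-empty TET subset")
    return subset


@dataclass(frozen=True)
class ModelStructure:
    """Which TET paralogs act in each of the three oxidation reactions.

    ``s1`` drives mdC->hmdC, ``s2`` drives hmdC->fdC, ``s3`` drives
    fdC->cadC. Each subset must be non-empty, otherwise the downstream
    cascade has no production and the structure is outside the candidate
    space.
    """

    s1: frozenset
    s2: frozenset
    s3: frozenset

    def __post_init__(self):
        object.__setattr__(self, "s1", _coerce_subset(self.s1))
        object.__setattr__(self, "s2", _coerce_subset(self.s2))
        object.__setattr__(self, "s3", _coerce_subset(self.s3))

    @classmethod
    def full(cls) -> "ModelStructure":
        """All three TETs active in all three reactions."""
        return cls(frozenset(TETS), frozenset(TETS), frozenset(TETS))

    @classmethod
    def from_masks(cls, m1: int, m2: int, m3: int) -> "ModelStructure":
        """Build from per-reaction bitmasks (bit 0 = TET1, bit 1 = TET2, bit 2 = TET3)."""
        subsets = []
        for mask in (m1, m2, m3):
            if not 1 <= mask <= 7:
                raise ValidationError(f"per-reaction bitmask must be in 1..7, got {mask}")
            subsets.append(frozenset(t for i, t in enumerate(TETS) if mask >> i & 1))
        return cls(*subsets)

    @property
    def subsets(self) -> tuple:
        return (self.s1, self.s2, self.s3)

    @property
    def masks(self) -> tuple:
        """Per-reaction bitmasks, TET1 = least significant bit."""
        return tuple(
            sum(1 << i for i, t in enumerate(TETS) if t in s) for s in self.subsets
        )

    def indicator(self, reaction: int) -> np.ndarray:
        """0/1 participation vector over (TET1, TET2, TET3) for reaction 0, 1 or 2."""
        s = self.subsets[reaction]
        return np.array([1.0 if t in s else 0.0 for t in TETS])


@dataclass(frozen=True)
class RateParameters:
    """Proportionality coefficients (enzyme-substrate affinities).

    Enzyme-coupled coefficients have units 1/(enzyme-level x time); k4 and
    k5 are plain first-order rates, 1/time. All must be non-negative (the
    NNLS fit never produces negative affinities). Coefficients of TETs
    excluded by the active structure are masked to zero at evaluation
    time; :meth:`masked` returns an explicitly zeroed copy.

    ``k_aid_hmdc`` multiplies hmdC deamination (f7) and ``k_aid_c``
    multiplies dC deamination (f10); the two may be tied to a single
    shared AID affinity by the estimation layer.
    """

    k_dnmt1: float = 1.0
    k1_tet1: float = 0.0
    k1_tet2: float = 0.0
    k1_tet3: float = 0.0
    k2_tet1: float = 0.0
    k2_tet2: float = 0.0
    k2_tet3: float = 0.0
    k3_tet1: float = 0.0
    k3_tet2: float = 0.0
    k3_tet3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k_aid_hmdc: float = 0.0
    k_aid_c: float = 0.0
    k_smug: float = 0.0
    k_tdg: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            object.__setattr__(self, f.name, float(getattr(self, f.name)))
        _validate_nonnegative_finite(self, [f.name for f in dataclasses.fields(self)])

    @property
    def k1(self) -> np.ndarray:
        return np.array([self.k1_tet1, self.k1_tet2, self.k1_tet3])

    @property
    def k2(self) -> np.ndarray:
        return np.array([self.k2_tet1, self.k2_tet2, self.k2_tet3])

    @property
    def k3(self) -> np.ndarray:
        return np.array([self.k3_tet1, self.k3_tet2, self.k3_tet3])

    def masked(self, structure: ModelStructure) -> "RateParameters":
        """Copy with coefficients of structure-excluded TETs set to exactly 0."""
        updates = {}
        for r, prefix in enumerate(("k1", "k2", "k3")):
            ind = structure.indicator(r)
            for i, t in enumerate(("tet1", "tet2", "tet3")):
                if not ind[i]:
                    updates[f"{prefix}_{t}"] = 0.0
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "RateParameters":
        return cls(**mapping)


@dataclass(frozen=True)
class FluxVector:
    """The ten fluxes f1..f10 (abundance per unit time)."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float
    f9: float
    f10: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"f{i}") for i in range(1, 11)])


def _linear_rates(enzymes: EnzymeProfile, params: RateParameters, structure: ModelStructure):
    """Per-unit-substrate removal/conversion rates implied by enzymes x parameters.

    Returns (a1, a2, a3, b_aid, r_smug, r_tdg): the three structure-masked
    TET oxidation rates, the AID deamination rate acting on hmdC, and the
    SMUG1/TDG repair rates.
    """
    tet = enzymes.tet_levels
    a1 = float(np.dot(params.k1 * structure.indicator(0), tet))
    a2 = float(np.dot(params.k2 * structure.indicator(1), tet))
    a3 = float(np.dot(params.k3 * structure.indicator(2), tet))
    b_aid = params.k_aid_hmdc * enzymes.aid
    r_smug = params.k_smug * enzymes.smug1
    r_tdg = params.k_tdg * enzymes.tdg
    return a1, a2, a3, b_aid, r_smug, r_tdg


def compute_fluxes(
    state: ModificationState,
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
) -> FluxVector:
    """Evaluate all ten fluxes at a given state.

    TET terms are summed only over the paralogs present in the structure's
    s1/s2/s3 subsets; every flux is non-negative for valid inputs.
    """
    a1, a2, a3, b_aid, r_smug, r_tdg = _linear_rates(enzymes, params, structure)
    return FluxVector(
        f1=params.k_dnmt1 * pool.C * enzymes.dnmt1,
        f2=a1 * state.mdC,
        f3=a2 * state.hmdC,
        f4=a3 * state.fdC,
        f5=params.k4 * state.fdC,
        f6=params.k5 * state.cadC,
        f7=b_aid * state.hmdC,
        f8=r_smug * state.hmdU,
        f9=r_tdg * state.U,
        f10=params.k_aid_c * pool.C * enzymes.aid,
    )


def time_derivatives(
    state: ModificationState,
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
) -> np.ndarray:
    """Right-hand side of the six ODEs in :data:`SPECIES` order."""
    f = compute_fluxes(state, enzymes, params, structure, pool)
    return np.array(
        [
            f.f1 - f.f2,
            f.f2 - f.f3 - f.f7,
            f.f3 - f.f4 - f.f5,
            f.f4 - f.f6,
            f.f7 - f.f8,
            f.f10 - f.f9,
        ]
    )


def system_matrix(
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
) -> np.ndarray:
    """Jacobian of the ODE right-hand side with respect to the state.

    Lower-triangular in the (mdC, hmdC, fdC, cadC, hmdU, U) ordering; each
    diagonal entry is the negated total removal rate of that species, so
    the eigenvalues are real and equal to the diagonal.
    """
    a1, a2, a3, b_aid, r_smug, r_tdg = _linear_rates(enzymes, params, structure)
    J = np.zeros((6, 6))
    J[0, 0] = -a1
    J[1, 0] = a1
    J[1, 1] = -(a2 + b_aid)
    J[2, 1] = a2
    J[2, 2] = -(a3 + params.k4)
    J[3, 2] = a3
    J[3, 3] = -params.k5
    J[4, 1] = b_aid
    J[4, 4] = -r_smug
    J[5, 5] = -r_tdg
    return J


def _constant_influx(enzymes: EnzymeProfile, params: RateParameters, pool: ExogenousPool) -> np.ndarray:
    """State-independent part of the right-hand side: f1 into mdC, f10 into U."""
    c = np.zeros(6)
    c[0] = params.k_dnmt1 * pool.C * enzymes.dnmt1
    c[5] = params.k_aid_c * pool.C * enzymes.aid
    return c


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues of the system matrix with stability/aperiodicity flags."""

    eigenvalues: np.ndarray
    stable: bool
    aperiodic: bool


def check_stability(
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    tol: float = 1e-12,
) -> StabilityReport:
    """Eigenvalue analysis of the system matrix.

    ``stable`` is True iff every eigenvalue has strictly negative real
    part; ``aperiodic`` iff all eigenvalues are (numerically) real. A
    species with zero total removal rate yields a zero eigenvalue and
    ``stable=False`` — reported, not raised.
    """
    J = system_matrix(enzymes, params, structure)
    eig = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(eig))) if eig.size else 1.0)
    stable = bool(np.all(eig.real < -tol * scale))
    aperiodic = bool(np.all(np.abs(eig.imag) <= tol * scale))
    return StabilityReport(eigenvalues=eig, stable=stable, aperiodic=aperiodic)


def _steady_state_array(
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool,
    on_zero_removal: str = "raise",
):
    """Closed-form steady state via the cascaded flux balances.

    With ``on_zero_removal="zero"`` a species whose removal rate vanishes
    is assigned level 0; if its production flux is positive the species
    name is recorded in the returned ``failed`` list (no finite steady
    state exists there).
    """
    a1, a2, a3, b_aid, r_smug, r_tdg = _linear_rates(enzymes, params, structure)
    f1 = params.k_dnmt1 * pool.C * enzymes.dnmt1
    f10 = params.k_aid_c * pool.C * enzymes.aid
    removals = (a1, a2 + b_aid, a3 + params.k4, params.k5, r_smug, r_tdg)
    failed: list[str] = []

    def divide(production: float, removal: float, species: str) -> float:
        if removal > 0.0:
            return production / removal
        if on_zero_removal == "raise":
            raise NoFiniteSteadyStateError(species)
        if production > 0.0:
            failed.append(species)
        return 0.0

    mdC = divide(f1, removals[0], "mdC")
    hmdC = divide(f1 if removals[0] > 0 else 0.0, removals[1], "hmdC")
    # hmdC at steady state receives f2 = f1 (whole methylation influx).
    f3 = a2 * hmdC
    f7 = b_aid * hmdC
    fdC = divide(f3, removals[2], "fdC")
    f4 = a3 * fdC
    cadC = divide(f4, removals[3], "cadC")
    hmdU = divide(f7, removals[4], "hmdU")
    U = divide(f10, removals[5], "U")
    return np.array([mdC, hmdC, fdC, cadC, hmdU, U]), failed


def steady_state(
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
) -> ModificationState:
    """Unique state at which all six derivatives vanish, in closed form.

    Cascades the balances f1=f2, f2=f3+f7, f3=f4+f5, f4=f6, f7=f8, f9=f10.
    Raises :class:`NoFiniteSteadyStateError` naming the species if any
    species has zero total removal rate.
    """
    values, _ = _steady_state_array(enzymes, params, structure, pool, on_zero_removal="raise")
    return ModificationState.from_array(values)


def is_steady(
    state: ModificationState,
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    threshold: float = 1e-10,
) -> bool:
    """Whether max |dx/dt| < threshold * (1 + |x|), componentwise."""
    dx = time_derivatives(state, enzymes, params, structure, pool)
    x = state.as_array()
    return bool(np.all(np.abs(dx) < threshold * (1.0 + np.abs(x))))


@dataclass(frozen=True)
class Trajectory:
    """Time course of the six state variables."""

    times: np.ndarray
    states: np.ndarray  # shape (n_points, 6), columns in SPECIES order

    def final_state(self) -> ModificationState:
        return ModificationState.from_array(self.states[-1])


def simulate(
    initial: ModificationState,
    enzymes: EnzymeProfile,
    params: RateParameters,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    horizon: float = 100.0,
    n_points: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the six ODEs from ``initial`` over ``[0, horizon]``.

    Uses a stiff-capable implicit method (BDF) with the constant Jacobian
    supplied analytically; removal rates across the cascade can differ by
    orders of magnitude, which makes the system stiff in practice.
    Trajectories stay non-negative (tiny integrator undershoots below
    ``atol`` are clipped to 0).
    """
    if horizon <= 0:
        raise ValidationError(f"horizon must be > 0, got {horizon}")
    if n_points < 2:
        raise ValidationError(f"n_points must be >= 2, got {n_points}")
    J = system_matrix(enzymes, params, structure)
    c = _constant_influx(enzymes, params, pool)
    t_eval = np.linspace(0.0, float(horizon), int(n_points))
    sol = solve_ivp(
        lambda t, x: J @ x + c,
        (0.0, float(horizon)),
        initial.as_array(),
        method="BDF",
        jac=lambda t, x: J,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed over horizon {horizon} for cell line "
            f"{enzymes.cell_line_id!r}: {sol.message}"
        )
    states = sol.y.T.copy()
    clip_band = 10.0 * atol
    states[(states < 0) & (states > -clip_band)] = 0.0
    return Trajectory(times=sol.t, states=states)
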