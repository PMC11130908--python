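"""Parameter estimation and structure selection from steady-state balances.

Measured modification levels are taken to be steady states of the
compartment model, so for every cell line *m* the flux balances

    f1 = f2,  f2 = f3 + f7,  f3 = f4 + f5,  f4 = f6,  f7 = f8,  f9 = f10

are linear in the rate coefficients once the measured levels and enzyme
levels are substituted. Stacking the balances over the training cell
lines gives a linear system ``A k = b`` that is solved by non-negative
least squares (affinities cannot be negative).

The raw balance system is homogeneous in the coefficients (zero is always
a solution), so a scale must be fixed. Convention: ``kDNMT1 = 1`` and
``C = 1`` — the methylation influx ``C * DNMT1_m`` becomes a known
right-hand side and every other coefficient is expressed in units of that
influx. By default the AID affinity is a single shared coefficient
multiplying both deamination fluxes (f7 and f10), which also makes the
dU-branch coefficients identifiable; ``tie_aid=False`` splits it into
separate hmdC- and dC-facing affinities.

Structures are compared by leave-one-cell-line-out cross-validation: fit
on M-1 lines, predict the held-out line's steady state from its enzyme
levels alone, and accumulate

    J_CV = 1/2 * sum_m sum_n (x_nm - d_nm)**2

over all M folds and the N observed state variables. All 343 candidate
structures are ranked ascending by J_CV, ties broken by canonical
structure code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .errors import ConditioningWarning, DegenerateSystemError, ValidationError
from .model import (
    SPECIES,
    TETS,
    EnzymeProfile,
    ExogenousPool,
    ModelStructure,
    ModificationState,
    RateParameters,
    _steady_state_array,
)
from .structures import FULL_STRUCTURE_INDEX, encode, enumerate_structures

__all__ = [
    "CellLineDataset",
    "DesignSystem",
    "FitResult",
    "StructureScore",
    "assemble_design",
    "fit_nnls",
    "predict_holdout",
    "performance_index",
    "cross_validate_structure",
    "rank_structures",
    "resubstitution_fit",
]

#: Ordered labels of the nine TET columns of a full-structure design.
_TET_COLUMNS = tuple(f"k{r}_{t}" for r in (1, 2, 3) for t in TETS)

#: Balance rows require these species to be observed (dU is optional).
_REQUIRED_SPECIES = ("mdC", "hmdC", "fdC", "cadC", "hmdU")

#: Performance indexes below this are floating-point residue on an exact
#: fit and are reported/ranked as zero.
ZERO_INDEX_TOL = 1e-12


@dataclass
class CellLineDataset:
    """Per-cell-line enzyme profiles and observed modification levels.

    ``observed_mask`` flags which of the six state variables were
    measured, in :data:`SPECIES` order; unobserved entries of the
    modification states are ignored by assembly and scoring.
    """

    cell_lines: list[str]
    enzymes: list[EnzymeProfile]
    observations: list[ModificationState]
    observed_mask: np.ndarray = field(default_factory=lambda: np.ones(6, dtype=bool))

    def __post_init__(self):
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (6,):
            raise ValidationError("observed_mask must have six entries, one per state variable")
        n = len(self.cell_lines)
        if len(self.enzymes) != n or len(self.observations) != n:
            raise ValidationError(
                "cell_lines, enzymes and observations must be keyed by the same IDs "
                f"(got lengths {n}, {len(self.enzymes)}, {len(self.observations)})"
            )
        if n < 1:
            raise ValidationError("dataset needs at least one cell line")
        if len(set(self.cell_lines)) != n:
            raise ValidationError("duplicate cell line IDs in dataset")

    @property
    def n_lines(self) -> int:
        return len(self.cell_lines)

    def subset(self, indices: Iterable[int]) -> "CellLineDataset":
        idx = list(indices)
        return CellLineDataset(
            cell_lines=[self.cell_lines[i] for i in idx],
            enzymes=[self.enzymes[i] for i in idx],
            observations=[self.observations[i] for i in idx],
            observed_mask=self.observed_mask.copy(),
        )

    def observation_matrix(self) -> np.ndarray:
        return np.vstack([o.as_array() for o in self.observations])


@dataclass
class DesignSystem:
    """Linear-in-parameters system A k = b built from steady-state balances."""

    A: np.ndarray
    b: np.ndarray
    columns: list[str]
    row_labels: list[str]
    structure: ModelStructure
    tie_aid: bool


@dataclass
class FitResult:
    """NNLS fit: parameters, residual, and conditioning diagnostics.

    ``resubstitution_mse`` is the training-set mean squared error between
    model steady-state predictions and observations (optimistically biased
    relative to cross-validation); it is filled by
    :func:`resubstitution_fit`, not by the bare solver.
    """

    params: RateParameters
    coefficients: dict
    residual_norm: float
    rank: int
    condition_number: float
    resubstitution_mse: Optional[float] = None
    notes: list[str] = field(default_factory=list)


@dataclass
class StructureScore:
    """A structure with its cross-validation performance."""

    structure: ModelStructure
    code: int
    j_cv: float
    predictions: np.ndarray  # (M, 6) held-out steady-state predictions
    observations: np.ndarray  # (M, 6) held-out measurements
    fold_failures: list  # per fold, species with no finite steady state
    n_folds: int
    n_states: int
    observed_mask: np.ndarray = field(default_factory=lambda: np.ones(6, dtype=bool))

    @property
    def any_failed_fold(self) -> bool:
        return any(len(f) > 0 for f in self.fold_failures)


def _design_columns(structure: ModelStructure, tie_aid: bool) -> list[str]:
    cols = [
        f"k{r + 1}_{t}"
        for r in range(3)
        for t in TETS
        if t in structure.subsets[r]
    ]
    cols += ["k4", "k5"]
    cols += ["kAID"] if tie_aid else ["kAID_hmdC", "kAID_C"]
    cols += ["kSMUG", "kTDG"]
    return cols


def assemble_design(
    dataset: CellLineDataset,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    tie_aid: bool = True,
    warn_conditioning: bool = True,
) -> DesignSystem:
    """Stack the steady-state balance rows of every cell line.

    Each cell line contributes one row per balance equation; the dU
    balance (f9 = f10) is included only when dU is observed. Under the
    ``kDNMT1 = 1`` convention the methylation influx ``C * DNMT1_m`` is
    the right-hand side of the f1 = f2 row; all other rows are
    homogeneous. Emits :class:`ConditioningWarning` if the stacked matrix
    is rank-deficient (e.g. proportional enzyme profiles across lines).
    """
    mask = dataset.observed_mask
    for sp in _REQUIRED_SPECIES:
        if not mask[SPECIES.index(sp)]:
            raise ValidationError(
                f"balance assembly requires observed {sp} levels; "
                f"only the dU balance may be dropped"
            )
    include_u = bool(mask[SPECIES.index("U")])
    columns = _design_columns(structure, tie_aid)
    col_index = {c: i for i, c in enumerate(columns)}
    aid_hmdc_col = "kAID" if tie_aid else "kAID_hmdC"
    aid_c_col = "kAID" if tie_aid else "kAID_C"

    rows, rhs, labels = [], [], []
    for line, enz, obs in zip(dataset.cell_lines, dataset.enzymes, dataset.observations):
        tet = enz.tet_levels

        def new_row():
            return np.zeros(len(columns))

        def add_tet_terms(row, reaction, level, sign):
            for i, t in enumerate(TETS):
                if t in structure.subsets[reaction]:
                    row[col_index[f"k{reaction + 1}_{t}"]] += sign * level * tet[i]

        # f1 = f2 : sum_{s1} k1_i TET_i mdC = kDNMT1 C DNMT1 (RHS, kDNMT1 = 1)
        row = new_row()
        add_tet_terms(row, 0, obs.mdC, +1.0)
        rows.append(row)
        rhs.append(pool.C * enz.dnmt1)
        labels.append(f"{line}:f1=f2")

        # f2 = f3 + f7
        row = new_row()
        add_tet_terms(row, 0, obs.mdC, +1.0)
        add_tet_terms(row, 1, obs.hmdC, -1.0)
        row[col_index[aid_hmdc_col]] += -obs.hmdC * enz.aid
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"{line}:f2=f3+f7")

        # f3 = f4 + f5
        row = new_row()
        add_tet_terms(row, 1, obs.hmdC, +1.0)
        add_tet_terms(row, 2, obs.fdC, -1.0)
        row[col_index["k4"]] += -obs.fdC
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"{line}:f3=f4+f5")

        # f4 = f6
        row = new_row()
        add_tet_terms(row, 2, obs.fdC, +1.0)
        row[col_index["k5"]] += -obs.cadC
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"{line}:f4=f6")

        # f7 = f8
        row = new_row()
        row[col_index[aid_hmdc_col]] += obs.hmdC * enz.aid
        row[col_index["kSMUG"]] += -obs.hmdU * enz.smug1
        rows.append(row)
        rhs.append(0.0)
        labels.append(f"{line}:f7=f8")

        # f9 = f10 (only with observed dU)
        if include_u:
            row = new_row()
            row[col_index["kTDG"]] += obs.U * enz.tdg
            row[col_index[aid_c_col]] += -pool.C * enz.aid
            rows.append(row)
            rhs.append(0.0)
            labels.append(f"{line}:f9=f10")

    A = np.vstack(rows)
    b = np.asarray(rhs)
    if warn_conditioning:
        rank = int(np.linalg.matrix_rank(A))
        if rank < len(columns):
            warnings.warn(
                f"design matrix is rank-deficient (rank {rank} < {len(columns)} columns); "
                "parameters are not all identifiable — check that enzyme profiles are "
                "not proportional across cell lines",
                ConditioningWarning,
                stacklevel=2,
            )
    return DesignSystem(A=A, b=b, columns=columns, row_labels=labels,
                        structure=structure, tie_aid=tie_aid)


def _params_from_coefficients(coefficients: dict, tie_aid: bool) -> RateParameters:
    kw = {"k_dnmt1": 1.0}
    for r in (1, 2, 3):
        for t in TETS:
            kw[f"k{r}_{t.lower()}"] = coefficients.get(f"k{r}_{t}", 0.0)
    kw["k4"] = coefficients.get("k4", 0.0)
    kw["k5"] = coefficients.get("k5", 0.0)
    if tie_aid:
        kw["k_aid_hmdc"] = kw["k_aid_c"] = coefficients.get("kAID", 0.0)
    else:
        kw["k_aid_hmdc"] = coefficients.get("kAID_hmdC", 0.0)
        kw["k_aid_c"] = coefficients.get("kAID_C", 0.0)
    kw["k_smug"] = coefficients.get("kSMUG", 0.0)
    kw["k_tdg"] = coefficients.get("kTDG", 0.0)
    return RateParameters(**kw)


def fit_nnls(system: DesignSystem) -> FitResult:
    """Solve min ||A k - b|| subject to k >= 0 and package the result."""
    A, b = system.A, system.b
    if A.size == 0:
        raise DegenerateSystemError("empty design matrix")
    if not np.any(A):
        raise DegenerateSystemError("all-zero design matrix: no parameter is constrained")
    x, rnorm = _scipy_nnls(A, b)
    sv = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * max(A.shape) * np.finfo(float).eps)) if sv.size else 0
    cond = float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else float("inf")
    coefficients = dict(zip(system.columns, x.tolist()))
    params = _params_from_coefficients(coefficients, system.tie_aid)
    notes = []
    if rank < len(system.columns):
        notes.append(f"rank-deficient design (rank {rank} of {len(system.columns)})")
    return FitResult(
        params=params,
        coefficients=coefficients,
        residual_norm=float(rnorm),
        rank=rank,
        condition_number=cond,
        notes=notes,
    )


def predict_holdout(
    params: RateParameters,
    enzymes: EnzymeProfile,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    policy: str = "zero",
) -> ModificationState:
    """Closed-form steady state of a held-out line under fitted parameters.

    If a fitted removal channel is zero the affected species has no finite
    steady state; ``policy="zero"`` scores it as level 0 (the fold is
    flagged by the cross-validation layer), ``policy="raise"`` propagates
    the error.
    """
    on_zero = "raise" if policy == "raise" else "zero"
    values, _ = _steady_state_array(enzymes, params, structure, pool, on_zero_removal=on_zero)
    return ModificationState.from_array(values)


def performance_index(
    predictions: Sequence,
    observations: Sequence,
    observed_mask: Optional[np.ndarray] = None,
) -> float:
    """J = 1/2 * sum over folds and observed states of squared errors."""
    if len(predictions) != len(observations):
        raise ValidationError(
            f"predictions ({len(predictions)}) and observations ({len(observations)}) "
            "must have equal lengths"
        )
    P = np.vstack([p.as_array() if isinstance(p, ModificationState) else np.asarray(p, float)
                   for p in predictions])
    D = np.vstack([d.as_array() if isinstance(d, ModificationState) else np.asarray(d, float)
                   for d in observations])
    mask = np.ones(P.shape[1], dtype=bool) if observed_mask is None else np.asarray(observed_mask, bool)
    resid = (P - D)[:, mask]
    return 0.5 * float(np.sum(resid**2))


def _fold_indices(n: int):
    for m in range(n):
        yield [i for i in range(n) if i != m], m


def _cv_scores(
    dataset: CellLineDataset,
    structures: Sequence[ModelStructure],
    pool: ExogenousPool,
    tie_aid: bool,
) -> list[StructureScore]:
    """Leave-one-line-out CV for many structures, sharing per-fold designs.

    The design of any sub-structure is the full-structure design with the
    masked TET columns removed, so the full design is assembled once per
    fold and column-selected per structure.
    """
    if dataset.n_lines < 2:
        raise ValidationError("cross-validation requires at least 2 cell lines")
    full = ModelStructure.full()
    folds = []
    for train_idx, test_idx in _fold_indices(dataset.n_lines):
        train = dataset.subset(train_idx)
        system = assemble_design(train, full, pool, tie_aid, warn_conditioning=False)
        folds.append((system, dataset.enzymes[test_idx], dataset.observations[test_idx]))
    full_columns = folds[0][0].columns
    tet_col_pos = {c: i for i, c in enumerate(full_columns)}
    extra_idx = [tet_col_pos[c] for c in full_columns if not c.startswith(("k1_", "k2_", "k3_"))]

    mask = dataset.observed_mask
    D = dataset.observation_matrix()
    scores = []
    for structure in structures:
        columns = _design_columns(structure, tie_aid)
        active = [tet_col_pos[c] for c in columns if c.startswith(("k1_", "k2_", "k3_"))]
        active += extra_idx
        P = np.zeros_like(D)
        failures = []
        for m, (system, enz_hold, _obs_hold) in enumerate(folds):
            A = system.A[:, active]
            x, _ = _scipy_nnls(A, system.b)
            params = _params_from_coefficients(dict(zip(columns, x.tolist())), tie_aid)
            values, failed = _steady_state_array(
                enz_hold, params, structure, pool, on_zero_removal="zero"
            )
            P[m] = values
            failures.append(failed)
        resid = (P - D)[:, mask]
        j_cv = 0.5 * float(np.sum(resid**2))
        scores.append(
            StructureScore(
                structure=structure,
                code=encode(structure),
                j_cv=j_cv,
                predictions=P,
                observations=D.copy(),
                fold_failures=failures,
                n_folds=dataset.n_lines,
                n_states=int(np.sum(mask)),
                observed_mask=mask.copy(),
            )
        )
    return scores


def cross_validate_structure(
    dataset: CellLineDataset,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    tie_aid: bool = True,
) -> StructureScore:
    """Leave-one-cell-line-out cross-validation of a single structure."""
    return _cv_scores(dataset, [structure], pool, tie_aid)[0]


def rank_structures(
    dataset: CellLineDataset,
    pool: ExogenousPool = ExogenousPool(),
    tie_aid: bool = True,
) -> list[StructureScore]:
    """Score all 343 structures and sort ascending by J_CV.

    Ties (which occur: distinct structures can reach identical indexes)
    are broken by the canonical structure code, so the ranking is fully
    deterministic. Indexes below ``ZERO_INDEX_TOL`` are floating-point
    noise on a perfect fit and are treated as exact ties, so on noiseless
    data the generating structure outranks its supersets by code.
    """
    scores = _cv_scores(dataset, enumerate_structures(), pool, tie_aid)
    scores.sort(key=lambda s: (s.j_cv if s.j_cv >= ZERO_INDEX_TOL else 0.0, s.code))
    return scores


def resubstitution_fit(
    dataset: CellLineDataset,
    structure: ModelStructure,
    pool: ExogenousPool = ExogenousPool(),
    tie_aid: bool = True,
) -> FitResult:
    """Fit on all lines and report the training (resubstitution) MSE.

    The index is the mean squared error between model steady-state
    predictions and observations over all lines and observed states. It
    is optimistically biased relative to cross-validation — with as many
    free coefficients as this model has, over-training is a real risk —
    and is reported for comparability, not for selection.
    """
    system = assemble_design(dataset, structure, pool, tie_aid)
    result = fit_nnls(system)
    mask = dataset.observed_mask
    D = dataset.observation_matrix()
    P = np.zeros_like(D)
    for m, enz in enumerate(dataset.enzymes):
        values, failed = _steady_state_array(
            enz, result.params, structure, pool, on_zero_removal="zero"
        )
        P[m] = values
        if failed:
            result.notes.append(f"line {dataset.cell_lines[m]}: no finite steady state for {failed}")
    resid = (P - D)[:, mask]
    result.resubstitution_mse = float(np.mean(resid**2))
    return result
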