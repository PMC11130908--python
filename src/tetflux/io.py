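"""Readers and writers for the tabular inputs and result reports.

Canonical dialect: UTF-8, tab-separated, header row, cell lines as rows.
The transposed layout (enzymes/species as rows, cell lines as columns —
the layout transcript tables are usually published in) is auto-detected
on read. Lines starting with ``#`` are metadata comments; every result
file embeds a JSON metadata header carrying the seed and a configuration
hash so it can be regenerated. Decimal separator is always the point,
independent of locale; the missing-value token ``NA`` is allowed only in
modification tables and only for wholly unobserved state columns.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import SPECIES, TETS, EnzymeProfile, ModificationState
from .selection import ZERO_INDEX_TOL, CellLineDataset, StructureScore
from .structures import FULL_STRUCTURE_INDEX

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_reference_enzymes",
    "write_ranked_results",
    "read_ranked_results",
    "write_prediction_table",
    "metadata_header",
]

_ENZYME_FIELDS = ("aid", "smug1", "tdg", "dnmt1", "tet1", "tet2", "tet3")

_ENZYME_ALIASES = {
    "aid": "aid",
    "smug": "smug1",
    "smug1": "smug1",
    "tdg": "tdg",
    "dnmt1": "dnmt1",
    "tet1": "tet1",
    "tet2": "tet2",
    "tet3": "tet3",
}

_STATE_ALIASES = {
    "5-mdc": "mdC", "5mdc": "mdC", "mdc": "mdC",
    "5-hmdc": "hmdC", "5hmdc": "hmdC", "hmdc": "hmdC",
    "5-fdc": "fdC", "5fdc": "fdC", "fdc": "fdC",
    "5-cadc": "cadC", "5cadc": "cadC", "cadc": "cadC",
    "5-hmdu": "hmdU", "5hmdu": "hmdU", "hmdu": "hmdU",
    "du": "U", "u": "U",
}

#: Column headers used when writing modification tables.
_STATE_HEADERS = {"mdC": "5-mdC", "hmdC": "5-hmdC", "fdC": "5-fdC",
                  "cadC": "5-cadC", "hmdU": "5-hmdU", "U": "dU"}

_ENZYME_HEADERS = {"aid": "AID", "smug1": "SMUG1", "tdg": "TDG", "dnmt1": "DNMT1",
                   "tet1": "TET1", "tet2": "TET2", "tet3": "TET3"}


def metadata_header(**payload) -> str:
    """One-line ``#`` comment with sorted-JSON metadata and its hash."""
    body = dict(payload)
    digest = hashlib.sha1(json.dumps(body, sort_keys=True).encode()).hexdigest()[:12]
    body["config_sha1"] = digest
    return "# tetflux " + json.dumps(body, sort_keys=True)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"table not found: {path}")
    first_data_line = next(
        (line for line in path.read_text().splitlines() if line and not line.startswith("#")),
        "",
    )
    sep = "\t" if "\t" in first_data_line else ","
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _orient(df: pd.DataFrame, aliases: dict, what: str) -> pd.DataFrame:
    """Return the table with cell lines as rows, fields as columns."""
    cols_known = sum(c.lower() in aliases for c in df.columns)
    rows_known = sum(str(r).lower() in aliases for r in df.index)
    if rows_known > cols_known:
        df = df.T
    return df


def _normalise_columns(df: pd.DataFrame, aliases: dict, path, what: str) -> pd.DataFrame:
    renamed = {}
    for c in df.columns:
        key = str(c).lower()
        if key not in aliases:
            raise ValidationError(f"{path}: unknown {what} column {c!r}")
        renamed[c] = aliases[key]
    df = df.rename(columns=renamed)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate {what} column(s) {dupes}")
    return df


def _check_numeric(df: pd.DataFrame, path, allow_na: bool) -> pd.DataFrame:
    df = df.apply(pd.to_numeric, errors="coerce") if allow_na else df.astype(float)
    for col in df.columns:
        for row, value in df[col].items():
            if pd.isna(value):
                if not allow_na:
                    raise ValidationError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
                continue
            if value < 0:
                raise ValidationError(
                    f"{path}: negative level {value!r} at row {row!r}, column {col!r}"
                )
    return df


def read_dataset(enzyme_table_path, modification_table_path) -> CellLineDataset:
    """Parse the enzyme and modification tables into a validated dataset.

    Both row and column orientations are accepted; state columns missing
    from the modification table (or wholly ``NA``) are recorded as
    unobserved in the dataset mask.
    """
    enz_df = _orient(_read_table(enzyme_table_path), _ENZYME_ALIASES, "enzyme")
    enz_df = _normalise_columns(enz_df, _ENZYME_ALIASES, enzyme_table_path, "enzyme")
    missing = set(_ENZYME_FIELDS) - set(enz_df.columns)
    if missing:
        raise ValidationError(f"{enzyme_table_path}: missing enzyme column(s) {sorted(missing)}")
    enz_df = _check_numeric(enz_df, enzyme_table_path, allow_na=False)

    mod_df = _orient(_read_table(modification_table_path), _STATE_ALIASES, "modification")
    mod_df = _normalise_columns(mod_df, _STATE_ALIASES, modification_table_path, "modification")
    mod_df = _check_numeric(mod_df, modification_table_path, allow_na=True)

    if set(enz_df.index) != set(mod_df.index):
        only_enz = sorted(set(enz_df.index) - set(mod_df.index))
        only_mod = sorted(set(mod_df.index) - set(enz_df.index))
        raise ValidationError(
            "cell line IDs differ between tables: "
            f"only in enzyme table {only_enz}, only in modification table {only_mod}"
        )
    mod_df = mod_df.loc[enz_df.index]

    observed = np.zeros(6, dtype=bool)
    for i, sp in enumerate(SPECIES):
        if sp not in mod_df.columns:
            continue
        col = mod_df[sp]
        if col.isna().all():
            continue
        if col.isna().any():
            bad = col.index[col.isna()].tolist()
            raise ValidationError(
                f"{modification_table_path}: column {sp!r} is partially NA (rows {bad}); "
                "NA is allowed only for wholly unobserved states"
            )
        observed[i] = True

    enzymes, observations = [], []
    for line in enz_df.index:
        enzymes.append(
            EnzymeProfile(**{f: float(enz_df.at[line, f]) for f in _ENZYME_FIELDS},
                          cell_line_id=str(line))
        )
        values = [
            float(mod_df.at[line, sp]) if observed[i] else 0.0
            for i, sp in enumerate(SPECIES)
        ]
        observations.append(ModificationState.from_array(values))
    return CellLineDataset(
        cell_lines=[str(line) for line in enz_df.index],
        enzymes=enzymes,
        observations=observations,
        observed_mask=observed,
    )


def _write_with_header(df: pd.DataFrame, path, meta: Optional[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write(meta + "\n")
        df.to_csv(fh, sep="\t", index=True, float_format="%.17g", lineterminator="\n")


def write_dataset(
    dataset: CellLineDataset,
    enzyme_table_path,
    modification_table_path,
    meta: Optional[str] = None,
) -> None:
    """Write the canonical (lines-as-rows) TSV pair; exact float round-trip."""
    enz = pd.DataFrame(
        {
            _ENZYME_HEADERS[f]: [getattr(e, f) for e in dataset.enzymes]
            for f in _ENZYME_FIELDS
        },
        index=pd.Index(dataset.cell_lines, name="cell_line"),
    )
    mod_cols = {}
    for i, sp in enumerate(SPECIES):
        header = _STATE_HEADERS[sp]
        if dataset.observed_mask[i]:
            mod_cols[header] = [getattr(o, sp) for o in dataset.observations]
        else:
            mod_cols[header] = ["NA"] * dataset.n_lines
    mod = pd.DataFrame(mod_cols, index=pd.Index(dataset.cell_lines, name="cell_line"))
    _write_with_header(enz, enzyme_table_path, meta)
    _write_with_header(mod, modification_table_path, meta)


def load_reference_enzymes() -> list[EnzymeProfile]:
    """The packaged reference transcript-level table as five profiles."""
    with resources.as_file(
        resources.files("tetflux.data").joinpath("enzyme_levels_reference.tsv")
    ) as path:
        df = _orient(_read_table(path), _ENZYME_ALIASES, "enzyme")
        df = _normalise_columns(df, _ENZYME_ALIASES, path, "enzyme")
        df = _check_numeric(df, path, allow_na=False)
    return [
        EnzymeProfile(**{f: float(df.at[line, f]) for f in _ENZYME_FIELDS},
                      cell_line_id=str(line))
        for line in df.index
    ]


_PATTERN_COLUMNS = tuple(
    f"{reaction}_{tet}"
    for reaction in ("mdC_to_hmdC", "hmdC_to_fdC", "fdC_to_cadC")
    for tet in TETS
)


def _pattern_cells(score: StructureScore) -> list[str]:
    cells = []
    for r in range(3):
        ind = score.structure.indicator(r)
        cells.extend("•" if ind[i] else "_" for i in range(3))
    return cells


def write_ranked_results(
    scores: Sequence[StructureScore],
    path,
    top_k: int = 10,
    meta: Optional[str] = None,
) -> pd.DataFrame:
    """Write the ranked-structure report: top-k rows plus full and worst.

    The table has the performance index, the canonical structure code and
    nine dot-pattern columns (3 reactions x TET1..TET3); the full
    structure and the worst structure are appended after the top-k block
    so the report always has ``top_k + 2`` data rows.
    """
    if not 1 <= top_k <= len(scores):
        raise ValidationError(f"top_k must be in [1, {len(scores)}], got {top_k}")
    ordered = sorted(
        scores,
        key=lambda s: (s.j_cv if s.j_cv >= ZERO_INDEX_TOL else 0.0, s.code),
    )
    try:
        full_idx = next(i for i, s in enumerate(ordered) if s.code == FULL_STRUCTURE_INDEX)
    except StopIteration:
        raise ValidationError("ranked report requires a score for the full structure") from None
    picks = [(i + 1, "", ordered[i]) for i in range(top_k)]
    picks.append((full_idx + 1, "full", ordered[full_idx]))
    picks.append((len(ordered), "worst", ordered[-1]))
    rows = []
    for rank, rank_note, score in picks:
        rows.append(
            {
                "rank": rank,
                "structure_code": score.code,
                "performance_index": f"{score.j_cv:.10e}",
                "note": rank_note,
                **dict(zip(_PATTERN_COLUMNS, _pattern_cells(score))),
            }
        )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write(meta + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return df


def read_ranked_results(path) -> pd.DataFrame:
    """Re-read a ranked-structure report (metadata comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_prediction_table(
    dataset: CellLineDataset,
    best: StructureScore,
    full: StructureScore,
    path,
    meta: Optional[str] = None,
) -> pd.DataFrame:
    """Per-cell-line observed vs cross-validated predicted levels.

    One row per (cell line, state variable): the measurement, the
    best-structure held-out prediction and the full-structure held-out
    prediction — the data behind a grouped-bar comparison figure.
    """
    rows = []
    for m, line in enumerate(dataset.cell_lines):
        for n, sp in enumerate(SPECIES):
            if not dataset.observed_mask[n]:
                continue
            rows.append(
                {
                    "cell_line": line,
                    "species": _STATE_HEADERS[sp],
                    "observed": best.observations[m, n],
                    "predicted_best": best.predictions[m, n],
                    "predicted_full": full.predictions[m, n],
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write(meta + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10e", lineterminator="\n")
    return df
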