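"""Consolidation and refinement of cross-link spectrum matches (XLSMs).

Responsibilities: parse per-search result tables (a documented TSV
dialect), rerank so each spectrum contributes at most one identification,
collapse to unique identifications (protein site x RNA product), and fit
a data-driven mass-error acceptance window.

TSV dialect
-----------
Mandatory columns: source_file, light_scan, heavy_scan, peptide, protein,
position, rna_composition, loss, adduct_mass_da, ld_score,
mass_error_ppm.  Optional: charge, search_group_id, rank.  Any column
prefixed ``score_`` is carried along as a named subscore.  The decoy flag
is derived solely from the protein-id prefix (default ``decoy_``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .adduct_chem import NucleotideComposition

__all__ = [
    "Xlsm",
    "IdentificationKey",
    "MassErrorModel",
    "DECOY_TAG",
    "MANDATORY_COLUMNS",
    "parse_search_results",
    "xlsms_to_frame",
    "write_xlsm_table",
    "rerank_by_scan",
    "rank_one",
    "collapse_to_unique_ids",
    "fit_mass_error_tolerance",
]

DECOY_TAG = "decoy_"

MANDATORY_COLUMNS = (
    "source_file",
    "light_scan",
    "heavy_scan",
    "peptide",
    "protein",
    "position",
    "rna_composition",
    "loss",
    "adduct_mass_da",
    "ld_score",
    "mass_error_ppm",
)


@dataclass(frozen=True)
class Xlsm:
    """One scored assignment of a spectrum (pair) to a peptide + adduct."""

    source_file: str
    light_scan: int
    heavy_scan: int
    peptide: str
    protein: str
    position: int
    rna_composition: str  # canonical tag, "" for light-only records
    loss: str
    adduct_mass_da: float
    ld_score: float
    mass_error_ppm: float
    is_decoy: bool
    charge: int = 0
    search_group_id: str = ""
    subscores: Mapping[str, float] = field(default_factory=dict)
    rank: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.ld_score):
            raise ValueError("ld_score must be finite")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def spectrum_key(self) -> Tuple[str, int, int]:
        return (self.source_file, self.light_scan, self.heavy_scan)

    @property
    def rna_length(self) -> int:
        if not self.rna_composition:
            return 0
        return NucleotideComposition.from_tag(self.rna_composition).length

    @property
    def identification_key(self) -> "IdentificationKey":
        return IdentificationKey(
            self.protein, self.position, self.rna_composition, self.loss
        )


@dataclass(frozen=True, order=True)
class IdentificationKey:
    """Unique identification: protein site x cross-linked RNA product."""

    protein: str
    position: int
    rna_composition: str
    loss: str


def parse_search_results(
    paths: Iterable, decoy_tag: str = DECOY_TAG,
    group_ids: Mapping[str, str] | None = None,
) -> List[Xlsm]:
    """Read one or more XLSM TSV files into typed records.

    ``group_ids`` optionally maps file path (string) -> search group id,
    used when the tables themselves lack a search_group_id column (the
    execution manifest provides this mapping).
    """
    records: List[Xlsm] = []
    for path in paths:
        df = pd.read_csv(
            path, sep="\t", dtype={"rna_composition": str, "loss": str},
            float_precision="round_trip",
        )
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        subscore_cols = [c for c in df.columns if c.startswith("score_")]
        default_group = (group_ids or {}).get(str(path), "")
        for idx, row in enumerate(df.itertuples(index=False), start=2):
            row = row._asdict()
            try:
                def _clean(v, default=""):
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        return default
                    return v

                comp = str(_clean(row["rna_composition"]))
                records.append(
                    Xlsm(
                        source_file=str(row["source_file"]),
                        light_scan=int(row["light_scan"]),
                        heavy_scan=int(row["heavy_scan"]),
                        peptide=str(row["peptide"]),
                        protein=str(row["protein"]),
                        position=int(row["position"]),
                        rna_composition=comp,
                        loss=str(row["loss"]),
                        adduct_mass_da=float(row["adduct_mass_da"]),
                        ld_score=float(row["ld_score"]),
                        mass_error_ppm=float(row["mass_error_ppm"]),
                        is_decoy=str(row["protein"]).startswith(decoy_tag),
                        charge=int(_clean(row.get("charge", 0), 0) or 0),
                        search_group_id=str(
                            _clean(row.get("search_group_id")) or default_group
                        ),
                        subscores={
                            c[len("score_"):]: float(row[c])
                            for c in subscore_cols
                        },
                        rank=int(_clean(row.get("rank", 0), 0) or 0),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable row {idx}: {exc}") from exc
    return records


def xlsms_to_frame(records: Sequence[Xlsm]) -> pd.DataFrame:
    """Flatten records (subscores as ``score_*`` columns) to a DataFrame."""
    subscore_names = sorted({k for r in records for k in r.subscores})
    rows = []
    for r in records:
        d = {
            "source_file": r.source_file,
            "light_scan": r.light_scan,
            "heavy_scan": r.heavy_scan,
            "peptide": r.peptide,
            "protein": r.protein,
            "position": r.position,
            "rna_composition": r.rna_composition,
            "loss": r.loss,
            "adduct_mass_da": r.adduct_mass_da,
            "ld_score": r.ld_score,
            "mass_error_ppm": r.mass_error_ppm,
            "is_decoy": r.is_decoy,
            "charge": r.charge,
            "search_group_id": r.search_group_id,
            "rank": r.rank,
        }
        for name in subscore_names:
            d[f"score_{name}"] = r.subscores.get(name, np.nan)
        rows.append(d)
    columns = list(MANDATORY_COLUMNS) + [
        "is_decoy", "charge", "search_group_id", "rank",
    ] + [f"score_{n}" for n in subscore_names]
    return pd.DataFrame(rows, columns=columns)


def write_xlsm_table(records: Sequence[Xlsm], path) -> None:
    xlsms_to_frame(records).to_csv(path, sep="\t", index=False)


def _rerank_sort_key(r: Xlsm):
    # ld desc, shorter RNA, lexicographic tag, target before decoy
    return (-r.ld_score, r.rna_length, r.rna_composition, r.is_decoy,
            r.loss, r.protein, r.position, r.peptide)


def rerank_by_scan(xlsms: Sequence[Xlsm]) -> List[Xlsm]:
    """Assign rank 1..n per spectrum key with a deterministic tie-break.

    Tie-break order: higher ld_score, then shorter RNA composition, then
    lexicographic composition tag, then target before decoy.  Output is
    sorted by spectrum key then rank, independent of input order, and the
    operation is idempotent.
    """
    by_key: Dict[Tuple[str, int, int], List[Xlsm]] = {}
    for r in xlsms:
        by_key.setdefault(r.spectrum_key, []).append(r)
    out: List[Xlsm] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=_rerank_sort_key)
        for i, r in enumerate(group, start=1):
            out.append(replace(r, rank=i))
    return out


def rank_one(xlsms: Sequence[Xlsm]) -> List[Xlsm]:
    """Keep only rank-1 records (input must already be reranked)."""
    return [r for r in xlsms if r.rank == 1]


def collapse_to_unique_ids(
    xlsms: Sequence[Xlsm],
) -> Dict[IdentificationKey, Xlsm]:
    """Best-scoring representative per unique identification key.

    Input is expected at rank-1 level; ties resolve by the rerank
    comparator so the result is permutation-invariant.
    """
    best: Dict[IdentificationKey, Xlsm] = {}
    for r in sorted(xlsms, key=_rerank_sort_key):
        key = r.identification_key
        if key not in best:
            best[key] = r
    return best


@dataclass(frozen=True)
class MassErrorModel:
    """Gaussian acceptance window fitted to observed ppm errors."""

    center_ppm: float
    spread_ppm: float
    low_ppm: float
    high_ppm: float
    n: int
    residual: float = float("nan")

    def contains(self, ppm: float) -> bool:
        return self.low_ppm <= ppm <= self.high_ppm

    def filter(self, xlsms: Sequence[Xlsm]) -> List[Xlsm]:
        return [r for r in xlsms if self.contains(r.mass_error_ppm)]


#: below this, the robust spread estimate is considered degenerate
_SPREAD_FLOOR_PPM = 0.1


def fit_mass_error_tolerance(
    targets: Sequence[Xlsm] | Sequence[float],
    n_sigma: float = 3.0,
    min_targets: int = 20,
) -> MassErrorModel:
    """Fit a Gaussian window to target mass errors (robust estimation).

    Center is the median; spread is 1.4826 x MAD (the Gaussian-consistent
    scale), floored at 0.1 ppm to survive degenerate inputs.  The window
    is ``center +/- n_sigma * spread``.  Decoy records should be excluded
    by the caller; passing raw floats is also supported.
    """
    errors = np.asarray(
        [
            r.mass_error_ppm if isinstance(r, Xlsm) else float(r)
            for r in targets
        ],
        dtype=float,
    )
    if len(errors) < min_targets:
        raise ValueError(
            f"only {len(errors)} target records (< {min_targets}); supply a "
            f"manual mass-error window instead"
        )
    center = float(np.median(errors))
    spread = float(1.4826 * np.median(np.abs(errors - center)))
    spread = max(spread, _SPREAD_FLOOR_PPM)
    resid = float(np.sqrt(np.mean((errors - center) ** 2)))
    return MassErrorModel(
        center_ppm=center,
        spread_ppm=spread,
        low_ppm=center - n_sigma * spread,
        high_ppm=center + n_sigma * spread,
        n=len(errors),
        residual=resid,
    )
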