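"""Protein-centric and RNA-centric summaries of filtered identifications."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .adduct_chem import NucleotideComposition, enumerate_compositions
from .results import IdentificationKey, Xlsm

__all__ = [
    "SiteAdductMatrix",
    "RnaPositionProfile",
    "site_adduct_counts",
    "rna_position_profile",
    "write_summary_csv",
    "SUMMARY_COLUMNS",
]


@dataclass
class SiteAdductMatrix:
    """Contingency of protein sites x RNA product tags."""

    table: pd.DataFrame  # index (protein, position), columns product tags
    mode: str = "count"

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def site_adduct_counts(ids: Sequence[Xlsm]) -> SiteAdductMatrix:
    """Count identifications per (protein, position) x RNA product.

    Input must be unique identifications (post-collapse); duplicate keys
    raise.  Row and column order is deterministic: (protein, position)
    ascending, product tags lexicographic.
    """
    seen = set()
    cells: Dict[Tuple[Tuple[str, int], str], int] = {}
    for r in ids:
        key = r.identification_key
        if key in seen:
            raise ValueError(f"duplicate identification key: {key}")
        seen.add(key)
        product = f"{r.rna_composition}:{r.loss}" if r.rna_composition else r.loss
        cells[((r.protein, r.position), product)] = (
            cells.get(((r.protein, r.position), product), 0) + 1
        )
    if not cells:
        return SiteAdductMatrix(pd.DataFrame())
    rows = sorted({site for site, _ in cells})
    cols = sorted({prod for _, prod in cells})
    data = np.zeros((len(rows), len(cols)), dtype=int)
    for (site, prod), n in cells.items():
        data[rows.index(site), cols.index(prod)] = n
    table = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(rows, names=["protein", "position"]),
        columns=cols,
    )
    return SiteAdductMatrix(table)


@dataclass
class RnaPositionProfile:
    """Per-nucleotide interaction weight over the input RNA sequence.

    In normalized mode each matched identification contributes exactly one
    unit of total positional weight, so ``weights.sum() + len(unmatched)
    == n_ids``; unnormalized, each window contributes its weight to every
    covered position (positional sum per id equals its RNA length).
    """

    sequence: str
    weights: np.ndarray  # length == len(sequence), 1-based positions
    normalized: bool
    unmatched: List[IdentificationKey] = field(default_factory=list)
    n_ids: int = 0
    window_weight: float = 0.0  # accumulated window weight (1 per match)


def rna_position_profile(
    ids: Sequence[Xlsm], rna_sequence: str, normalize: bool = False
) -> RnaPositionProfile:
    """Distribute each identification's weight over compatible RNA windows.

    For an identification with RNA composition c, every contiguous window
    of the sequence whose base composition equals c receives weight
    1/#windows; each covered nucleotide position accrues the window's
    weight (divided by window length when ``normalize`` is set, so each
    identification deposits one unit of positional weight in total).
    Identifications with no compatible window are reported in
    ``unmatched`` rather than silently dropped.
    """
    seq = rna_sequence.strip().upper()
    NucleotideComposition.from_sequence(seq)  # validates alphabet
    weights = np.zeros(len(seq), dtype=float)
    unmatched: List[IdentificationKey] = []
    window_weight = 0.0
    for r in ids:
        if not r.rna_composition:
            unmatched.append(r.identification_key)
            continue
        comp = NucleotideComposition.from_tag(r.rna_composition)
        k = comp.length
        windows = [
            i
            for i in range(len(seq) - k + 1)
            if NucleotideComposition.from_sequence(seq[i : i + k]) == comp
        ]
        if not windows:
            unmatched.append(r.identification_key)
            continue
        w = 1.0 / len(windows)
        pos_w = w / k if normalize else w
        for i in windows:
            weights[i : i + k] += pos_w
            window_weight += w
    return RnaPositionProfile(
        sequence=seq,
        weights=weights,
        normalized=normalize,
        unmatched=unmatched,
        n_ids=len(ids),
        window_weight=window_weight,
    )


SUMMARY_COLUMNS = (
    "protein",
    "position",
    "peptide",
    "rna_composition",
    "loss",
    "adduct_mass_da",
    "ld_score",
    "q_value",
    "n_supporting_xlsms",
)


def write_summary_csv(
    ids: Sequence[Xlsm],
    path,
    q_values: Mapping[IdentificationKey, float] | None = None,
    support: Mapping[IdentificationKey, int] | None = None,
) -> None:
    """Minimum-information CSV for downstream structural modeling.

    One row per identification; RFC-4180 quoting via the csv module; the
    header is always written, even for empty input.
    """
    q_values = q_values or {}
    support = support or {}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for r in sorted(ids, key=lambda x: x.identification_key):
            key = r.identification_key
            writer.writerow(
                [
                    r.protein,
                    r.position,
                    r.peptide,
                    r.rna_composition,
                    r.loss,
                    f"{r.adduct_mass_da:.6f}",
                    f"{r.ld_score:.4f}",
                    f"{q_values.get(key, float('nan')):.6g}",
                    support.get(key, 1),
                ]
            )
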