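"""False-discovery-rate control for consolidated identifications.

Three strategies:

* ``observed_fdr`` — classic target-decoy competition at the unique
  identification level: FDR(t) = D(t) / T(t) with counts at score >= t
  (the monolink convention), plus a monotone q-value per score.
* ``transferred_fdr`` — per-RNA-composition-bin thresholds obtained by
  apportioning the global decoy count to each bin via a through-origin
  linear fit of bin-vs-global cumulative decoy counts over the lowest 80%
  of unique decoy scores, with an observed-FDR fallback for bins where
  the fit is undefined or under-supported.
* ``export_pin`` — Percolator/mokapot-compatible PIN export so an
  external semi-supervised rescorer can be applied; the rescoring itself
  is out of scope here.

The q-value of a score s is min over thresholds t <= s of FDR(t): the
smallest FDR at which an identification scoring s would be accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .results import Xlsm

__all__ = [
    "FdrCurve",
    "BinThreshold",
    "observed_fdr",
    "apply_fdr_threshold",
    "transferred_fdr",
    "export_pin",
    "read_pin",
    "PIN_FIXED_FEATURES",
]


@dataclass(frozen=True)
class FdrCurve:
    """Step curve of target/decoy counts, FDR and q-value per threshold.

    ``scores`` is ascending; at each score t, ``target_counts`` and
    ``decoy_counts`` are the unique-ID counts with score >= t.  ``fdr``
    is D/T clipped to [0, 1] (1.0 where T = 0), and ``qvalue`` is the
    running minimum of FDR over thresholds <= t, hence non-increasing as
    the score increases.
    """

    scores: np.ndarray
    target_counts: np.ndarray
    decoy_counts: np.ndarray
    fdr: np.ndarray
    qvalue: np.ndarray

    def q_at(self, score: float) -> float:
        """q-value of an identification scoring ``score`` (step lookup)."""
        idx = np.searchsorted(self.scores, score, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.qvalue[idx])


def _scores_labels(
    ids: Sequence,
) -> Tuple[np.ndarray, np.ndarray]:
    scores, decoys = [], []
    for item in ids:
        if isinstance(item, Xlsm):
            scores.append(item.ld_score)
            decoys.append(item.is_decoy)
        else:
            s, d = item[0], item[1]
            scores.append(float(s))
            decoys.append(bool(d))
    return np.asarray(scores, dtype=float), np.asarray(decoys, dtype=bool)


def observed_fdr(ids: Sequence) -> FdrCurve:
    """Target-decoy FDR curve over all observed score thresholds.

    ``ids`` is a sequence of Xlsm records or (score, is_decoy) pairs at
    the unique-identification level.
    """
    scores, decoys = _scores_labels(ids)
    if len(scores) == 0:
        raise ValueError("no identifications supplied")
    if not (~decoys).any():
        raise ValueError("no target identifications supplied")
    thresholds = np.unique(scores)  # ascending
    # counts with score >= t for each threshold t
    order = np.sort(scores[~decoys])
    target_counts = len(order) - np.searchsorted(order, thresholds, side="left")
    order_d = np.sort(scores[decoys])
    decoy_counts = len(order_d) - np.searchsorted(order_d, thresholds, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            target_counts > 0, decoy_counts / np.maximum(target_counts, 1), 1.0
        )
    fdr = np.clip(fdr, 0.0, 1.0)
    qvalue = np.minimum.accumulate(fdr)  # running min from low t upward
    return FdrCurve(
        scores=thresholds,
        target_counts=target_counts.astype(int),
        decoy_counts=decoy_counts.astype(int),
        fdr=fdr,
        qvalue=qvalue,
    )


def apply_fdr_threshold(
    curve: FdrCurve, ids: Sequence, alpha: float = 0.01
) -> Tuple[List, float | None, str]:
    """Filter target identifications at q < alpha.

    The cutoff is the lowest *target* score whose q-value is below alpha;
    all target identifications scoring >= cutoff pass (decoys are the
    measurement device and are never returned).  Returns
    ``(passed, cutoff, status)`` where status is "ok" or "nothing_passes".
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    scores, decoys = _scores_labels(ids)
    target_scores = np.unique(scores[~decoys])
    cutoff = None
    for t in target_scores:  # ascending: first hit is the lowest cutoff
        if curve.q_at(t) < alpha:
            cutoff = float(t)
            break
    if cutoff is None:
        return [], None, "nothing_passes"
    passed = [
        item
        for item, s, d in zip(ids, scores, decoys)
        if not d and s >= cutoff
    ]
    return passed, cutoff, "ok"


@dataclass(frozen=True)
class BinThreshold:
    """Per-RNA-composition score cutoff at the requested FDR."""

    bin_key: str
    cutoff: float | None
    method: str  # "transferred" or "fallback_observed"
    n_decoys_in_bin: int
    pi_bin: float = float("nan")


def _bin_key_of(item) -> str:
    if isinstance(item, Xlsm):
        return item.rna_composition
    return str(item[2])


def transferred_fdr(
    ids: Sequence,
    alpha: float = 0.01,
    decoy_quantile: float = 0.80,
    min_bin_decoys: int = 10,
) -> List[BinThreshold]:
    """Per-bin score thresholds via decoy-share transfer.

    ``ids`` holds unique-level identifications: Xlsm records (binned by
    RNA composition tag) or (score, is_decoy, bin_key) triples.  For each
    bin b the decoy share pi_b is the slope of a through-origin least
    squares fit of the bin's cumulative unique-decoy count against the
    global cumulative unique-decoy count, evaluated at thresholds
    spanning the lowest ``decoy_quantile`` of unique decoy scores
    (computed globally).  The bin's transferred FDR at threshold t is
    ``pi_b * D_global(t) / T_b(t)`` and the cutoff is the lowest t (over
    the bin's target scores) with transferred FDR < alpha.  Bins with
    fewer than ``min_bin_decoys`` decoys in the fit region, or where the
    fit or ratio is undefined, or where no threshold qualifies, fall back
    to the global observed-FDR cutoff (method = "fallback_observed").
    """
    scores, decoys = _scores_labels(ids)
    bins = np.array([_bin_key_of(item) for item in ids])
    curve = observed_fdr(ids)
    _, global_cutoff, _ = apply_fdr_threshold(curve, ids, alpha=alpha)

    decoy_scores = np.sort(scores[decoys])
    out: List[BinThreshold] = []

    if len(decoy_scores) == 0:
        for key in sorted(set(bins)):
            out.append(
                BinThreshold(key, global_cutoff, "fallback_observed", 0)
            )
        return out

    # fit region: thresholds over the lowest `decoy_quantile` of unique
    # decoy score values (global), to avoid sparse high-score counts
    unique_decoy_scores = np.unique(decoy_scores)
    q_cut = np.quantile(unique_decoy_scores, decoy_quantile)
    fit_thresholds = unique_decoy_scores[unique_decoy_scores <= q_cut]

    def count_ge(sorted_vals: np.ndarray, ts: np.ndarray) -> np.ndarray:
        return len(sorted_vals) - np.searchsorted(sorted_vals, ts, side="left")

    d_global_fit = count_ge(decoy_scores, fit_thresholds).astype(float)

    for key in sorted(set(bins)):
        in_bin = bins == key
        bin_decoy_scores = np.sort(scores[decoys & in_bin])
        n_bin_decoys_fit = int(np.sum(bin_decoy_scores <= q_cut))
        bin_target_scores = np.sort(scores[~decoys & in_bin])

        usable = (
            len(fit_thresholds) > 0
            and n_bin_decoys_fit >= min_bin_decoys
            and len(bin_target_scores) > 0
            and float(np.sum(d_global_fit**2)) > 0
        )
        if not usable:
            out.append(
                BinThreshold(
                    key, global_cutoff, "fallback_observed",
                    len(bin_decoy_scores),
                )
            )
            continue

        d_bin_fit = count_ge(bin_decoy_scores, fit_thresholds).astype(float)
        pi_bin = float(
            np.sum(d_bin_fit * d_global_fit) / np.sum(d_global_fit**2)
        )

        # transferred FDR curve on the global score grid, with a running
        # minimum so the single-bin case reduces exactly to observed FDR
        grid = curve.scores  # ascending
        t_b = count_ge(bin_target_scores, grid).astype(float)
        d_g = count_ge(decoy_scores, grid).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr_b = np.where(t_b > 0, pi_bin * d_g / np.maximum(t_b, 1), 1.0)
        fdr_b = np.clip(fdr_b, 0.0, None)
        q_b = np.minimum.accumulate(fdr_b)

        cutoff = None
        for t in np.unique(bin_target_scores):  # ascending
            idx = np.searchsorted(grid, t, side="right") - 1
            if idx >= 0 and q_b[idx] < alpha:
                cutoff = float(t)
                break
        if cutoff is None:
            out.append(
                BinThreshold(
                    key, global_cutoff, "fallback_observed",
                    len(bin_decoy_scores), pi_bin,
                )
            )
        else:
            out.append(
                BinThreshold(
                    key, cutoff, "transferred",
                    len(bin_decoy_scores), pi_bin,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Percolator PIN export

PIN_FIXED_FEATURES = (
    "ld_score",
    "rna_mass",
    "rna_length",
    "mass_error_ppm",
    "charge",
    "peptide_length",
)


def export_pin(xlsms: Sequence[Xlsm], path) -> pd.DataFrame:
    """Write rank-1 XLSMs as a Percolator-compatible PIN file.

    Columns: SpecId, Label (+1/-1), ScanNr, the fixed feature block
    (ld_score, rna_mass = calculated adduct mass, rna_length,
    mass_error_ppm, charge, peptide_length), every ingested subscore
    verbatim, then Peptide (dotted notation) and Proteins.  All feature
    values must be finite; missing subscores raise with the row index.
    """
    if len(xlsms) == 0:
        raise ValueError("no records to export")
    subscore_names = sorted({k for r in xlsms for k in r.subscores})
    rows = []
    for i, r in enumerate(xlsms):
        feats: Dict[str, float] = {
            "ld_score": r.ld_score,
            "rna_mass": r.adduct_mass_da,
            "rna_length": float(r.rna_length),
            "mass_error_ppm": r.mass_error_ppm,
            "charge": float(r.charge),
            "peptide_length": float(len(r.peptide)),
        }
        for name in subscore_names:
            if name not in r.subscores:
                raise ValueError(f"row {i}: missing subscore {name!r}")
            feats[name] = float(r.subscores[name])
        for name, v in feats.items():
            if not math.isfinite(v):
                raise ValueError(f"row {i}: non-finite feature {name!r}")
        rows.append(
            {
                "SpecId": f"{r.source_file}.{r.light_scan}.{r.heavy_scan}."
                          f"{r.charge}_{i}",
                "Label": -1 if r.is_decoy else 1,
                "ScanNr": r.light_scan,
                **feats,
                "Peptide": f"-.{r.peptide}.-",
                "Proteins": r.protein,
            }
        )
    columns = (
        ["SpecId", "Label", "ScanNr"]
        + list(PIN_FIXED_FEATURES)
        + subscore_names
        + ["Peptide", "Proteins"]
    )
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_pin(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ("SpecId", "Label", "ScanNr", "Peptide", "Proteins")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PIN file missing column(s): {', '.join(missing)}")
    if not set(df["Label"].unique()) <= {1, -1}:
        raise ValueError("PIN Label column must contain only +1/-1")
    return df
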