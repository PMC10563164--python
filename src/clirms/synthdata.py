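"""Synthetic data generation for closed-loop testing of the pipeline.

Emulates the statistical structure real runs exhibit, without any raw
data: bimodal target score distributions whose high mode shifts lower as
the RNA adduct gets longer, a unimodal low-scoring decoy distribution
independent of RNA length, precursor runs carrying light/heavy scan pairs
at specified delta masses within ppm/RT tolerances, and control runs with
no pairs and no true targets.

Everything is driven by :class:`SyntheticConfig`; identical config + seed
produces byte-identical output.  The XLSM tables use the same TSV dialect
the results module reads, so the generator is the fixture contract for
the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .adduct_chem import (
    DEFAULT_LOSSES,
    NucleotideComposition,
    build_adduct_species,
    enumerate_compositions,
)
from .results import Xlsm
from .spectra import MzxmlScan, write_mzxml

__all__ = [
    "SyntheticConfig",
    "fox1_like",
    "simulate_xlsm_table",
    "simulate_precursor_run",
]

_AMINO = "ACDEFGHIKLMNPQSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic generator.

    Score model: true targets draw from Normal(true_mean_base -
    true_mean_per_nt * (rna_length - 1), true_sd); chance targets and
    decoys draw iid from Normal(null_mean, null_sd).  Keeping
    n_chance_targets == n_decoys makes the decoy counts an unbiased
    estimate of chance-target counts, which is what target-decoy FDR
    assumes.
    """

    seed: int = 0
    rna_sequence: str = "UGCAUGU"
    protein: str = "FOX1"
    n_true_targets: int = 400
    n_chance_targets: int = 800
    n_decoys: int = 800
    min_rna_len: int = 1
    max_rna_len: int = 4
    true_mean_base: float = 32.0
    true_mean_per_nt: float = 1.5
    true_sd: float = 3.0
    null_mean: float = 12.0
    null_sd: float = 3.5
    mass_error_mean_ppm: float = 1.5
    mass_error_sd_ppm: float = 1.0
    # precursor-run parameters
    n_pairs: int = 25
    n_background: int = 100
    pair_deltas: Tuple[float, ...] = (11.024263, 23.045562)
    ppm_tol: float = 10.0
    rt_tol_s: float = 60.0
    pair_ppm_jitter: float = 3.0
    pair_rt_jitter_s: float = 20.0
    control_run: bool = False

    def validate(self) -> None:
        if min(self.n_true_targets, self.n_chance_targets, self.n_decoys) < 0:
            raise ValueError("counts must be >= 0")
        if min(self.true_sd, self.null_sd, self.mass_error_sd_ppm) <= 0:
            raise ValueError("spreads must be > 0")


def fox1_like(seed: int = 0, **overrides) -> SyntheticConfig:
    """Preset resembling a small single-protein RRM/RNA experiment."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def _random_peptide(rng: np.random.Generator) -> str:
    n = int(rng.integers(6, 15))
    body = "".join(rng.choice(list(_AMINO), size=n))
    return body + rng.choice(["K", "R"])


def _compositions(cfg: SyntheticConfig) -> List[NucleotideComposition]:
    comps = enumerate_compositions(
        cfg.rna_sequence, cfg.min_rna_len,
        min(cfg.max_rna_len, len(cfg.rna_sequence)),
    )
    return sorted(comps, key=lambda c: (c.length, c.tag))


def simulate_xlsm_table(
    cfg: SyntheticConfig,
) -> Tuple[List[Xlsm], List[bool]]:
    """Generate one consolidated XLSM table plus hidden truth labels.

    Returns ``(records, is_true)`` where ``is_true[i]`` marks records
    drawn from the high-scoring (true cross-link) component.  Sites are
    unique per record so the table is already at unique-identification
    level.  Subscores are noisy monotone transforms of the ld-score so
    PIN export is exercised meaningfully.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    comps = _compositions(cfg)
    masses = {
        c.tag: build_adduct_species(c, DEFAULT_LOSSES[0], "metabolic_13C15N")
        for c in comps
    }

    n_true = 0 if cfg.control_run else cfg.n_true_targets
    records: List[Xlsm] = []
    truth: List[bool] = []
    scan = 1000
    position = 1

    def emit(is_true: bool, is_decoy: bool) -> None:
        nonlocal scan, position
        comp = comps[int(rng.integers(len(comps)))]
        if is_true:
            mu = cfg.true_mean_base - cfg.true_mean_per_nt * (comp.length - 1)
            ld = float(rng.normal(mu, cfg.true_sd))
        else:
            ld = float(rng.normal(cfg.null_mean, cfg.null_sd))
        species = masses[comp.tag]
        subs = {
            "xcorrb": ld * 0.04 + float(rng.normal(0, 0.05)),
            "xcorrx": ld * 0.05 + float(rng.normal(0, 0.05)),
            "tic": 1.0 / (1.0 + np.exp(-(ld - 20.0) / 5.0))
            + float(rng.normal(0, 0.02)),
        }
        protein = (
            f"decoy_{cfg.protein}" if is_decoy else cfg.protein
        )
        records.append(
            Xlsm(
                source_file="synthetic.mzXML",
                light_scan=scan,
                heavy_scan=scan + 1,
                peptide=_random_peptide(rng),
                protein=protein,
                position=position,
                rna_composition=comp.tag,
                loss="none",
                adduct_mass_da=species.light_mass_da,
                ld_score=round(ld, 4),
                mass_error_ppm=round(
                    float(
                        rng.normal(
                            cfg.mass_error_mean_ppm, cfg.mass_error_sd_ppm
                        )
                    ),
                    4,
                ),
                is_decoy=is_decoy,
                charge=int(rng.integers(2, 5)),
                search_group_id="",
                subscores={k: round(v, 5) for k, v in subs.items()},
            )
        )
        truth.append(is_true)
        scan += 2
        position += 1

    for _ in range(n_true):
        emit(True, False)
    for _ in range(cfg.n_chance_targets):
        emit(False, False)
    for _ in range(cfg.n_decoys):
        emit(False, True)
    return records, truth


def _pairs_with(
    mz: float, z: int, rt: float,
    accepted: Sequence[Tuple[float, int, float]],
    deltas: Sequence[float],
    ppm_margin: float,
    rt_margin: float,
) -> bool:
    """True if (mz, z, rt) could form a pair with any accepted precursor."""
    for mz2, z2, rt2 in accepted:
        if z2 != z or abs(rt2 - rt) > rt_margin:
            continue
        neutral = min(mz, mz2) * z
        offset = abs(mz - mz2) * z
        for d in deltas:
            if abs(offset - d) / neutral * 1e6 < ppm_margin:
                return True
    return False


def simulate_precursor_run(
    cfg: SyntheticConfig, mzxml_path
) -> List[Dict[str, object]]:
    """Write a synthetic mzXML run; return the injected-pair ledger.

    Injected pairs have delta-mass ppm error <= pair_ppm_jitter and RT
    gap <= pair_rt_jitter_s (both kept at or below half the matching
    tolerances by default).  Background precursors are rejection-sampled
    so none sits within three ppm-tolerances of a valid pair offset to
    any other precursor.  ``control_run=True`` injects no pairs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    deltas = sorted(cfg.pair_deltas)
    ppm_margin = 3.0 * cfg.ppm_tol
    rt_margin = 2.0 * cfg.rt_tol_s

    accepted: List[Tuple[float, int, float]] = []  # (mz, z, rt)
    scans: List[MzxmlScan] = []
    ledger: List[Dict[str, object]] = []
    scan_num = 1

    def add_scan(mz: float, z: int, rt: float) -> int:
        nonlocal scan_num
        num = scan_num
        n_frag = int(rng.integers(5, 12))
        frag_mz = np.sort(rng.uniform(150.0, mz * z, size=n_frag))
        frag_int = rng.uniform(1e3, 1e6, size=n_frag)
        scans.append(
            MzxmlScan(
                num=num, ms_level=2, retention_time_s=rt,
                mz=frag_mz, intensity=frag_int,
                precursor_mz=mz, precursor_charge=z,
            )
        )
        accepted.append((mz, z, rt))
        scan_num += 1
        return num

    n_pairs = 0 if cfg.control_run else cfg.n_pairs
    for _ in range(n_pairs):
        for _attempt in range(10_000):
            z = int(rng.integers(2, 4))
            light_mz = float(rng.uniform(400.0, 1100.0))
            rt = float(rng.uniform(120.0, 3000.0))
            d = float(rng.choice(deltas))
            jitter_ppm = float(rng.uniform(-1, 1)) * cfg.pair_ppm_jitter
            heavy_mz = light_mz + d / z + jitter_ppm * 1e-6 * light_mz
            rt_gap = float(rng.uniform(0, cfg.pair_rt_jitter_s))
            if _pairs_with(
                light_mz, z, rt, accepted, deltas, ppm_margin, rt_margin
            ) or _pairs_with(
                heavy_mz, z, rt + rt_gap, accepted, deltas, ppm_margin,
                rt_margin,
            ):
                continue
            light_scan = add_scan(light_mz, z, rt)
            heavy_scan = add_scan(heavy_mz, z, rt + rt_gap)
            ledger.append(
                {
                    "light_scan": light_scan,
                    "heavy_scan": heavy_scan,
                    "delta_mass_da": d,
                    "charge": z,
                    "light_mz": light_mz,
                    "heavy_mz": heavy_mz,
                }
            )
            break
        else:
            raise RuntimeError("could not place an injected pair")

    for _ in range(cfg.n_background):
        for _attempt in range(10_000):
            z = int(rng.integers(2, 4))
            mz = float(rng.uniform(400.0, 1100.0))
            rt = float(rng.uniform(120.0, 3000.0))
            if _pairs_with(mz, z, rt, accepted, deltas, ppm_margin, rt_margin):
                continue
            add_scan(mz, z, rt)
            break
        else:
            raise RuntimeError("could not place a background precursor")

    scans.sort(key=lambda s: s.num)
    write_mzxml(scans, mzxml_path)
    return ledger
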