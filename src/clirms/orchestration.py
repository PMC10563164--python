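"""Parallel-search setup: parameter file trees, light-only searches,
and decoy protein databases.

The parameter documents use a documented key=value text format (one
``monolinkmass=<light>,<delta>`` line per member species) rather than any
engine-native dialect; ``param_writer`` hooks allow emitting alternative
dialects.  The manifest is a TSV with columns group_id, delta_mass_da,
param_path, light_only, spectra_group.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .adduct_chem import SearchGroupDefinition

__all__ = [
    "SearchConfig",
    "ParameterFileSet",
    "generate_search_params",
    "generate_light_only_search",
    "make_decoy_db",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = (
    "group_id",
    "delta_mass_da",
    "param_path",
    "light_only",
    "spectra_group",
)


@dataclass
class SearchConfig:
    """Engine-agnostic description of one search campaign."""

    fasta_paths: Sequence[str]
    rna_sequence: str
    scheme: str = "metabolic_13C15N"
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    precursor_tol_ppm: float = 10.0
    fragment_tol_common_da: float = 0.2
    fragment_tol_xlink_da: float = 0.3
    spectrum_files: Sequence[str] = ()
    spectra_groups: Dict[str, str] = field(default_factory=dict)
    output_dir: str = "."

    def validate(self) -> None:
        if not self.rna_sequence or not self.rna_sequence.strip():
            raise ValueError("empty RNA sequence")
        if self.precursor_tol_ppm <= 0:
            raise ValueError("precursor tolerance must be > 0")
        if self.fragment_tol_common_da <= 0 or self.fragment_tol_xlink_da <= 0:
            raise ValueError("fragment tolerances must be > 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("missed cleavages must be >= 0")
        if not self.spectrum_files:
            raise ValueError("at least one spectrum file is required")

    @classmethod
    def from_yaml(cls, path) -> "SearchConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class ParameterFileSet:
    """Paths of generated parameter documents plus the manifest."""

    root: Path
    manifest_path: Path
    entries: List[Dict[str, object]] = field(default_factory=list)


def _default_param_writer(
    config: SearchConfig, group: SearchGroupDefinition, light_only: bool
) -> str:
    lines = [
        f"group_id={group.group_id}",
        f"delta_mass_da={group.delta_mass_da:.6f}",
        f"light_only={'true' if light_only else 'false'}",
        f"require_isotope_pair={'false' if light_only else 'true'}",
        f"database={';'.join(str(p) for p in config.fasta_paths)}",
        f"enzyme={config.enzyme}",
        f"max_missed_cleavages={config.max_missed_cleavages}",
        f"precursor_tol_ppm={config.precursor_tol_ppm:g}",
        f"fragment_tol_common_da={config.fragment_tol_common_da:g}",
        f"fragment_tol_xlink_da={config.fragment_tol_xlink_da:g}",
        f"scheme={config.scheme}",
    ]
    if light_only:
        lines.append("monolinkmass=0.000000,0.000000")
    else:
        for sp in group.members:
            lines.append(
                f"monolinkmass={sp.light_mass_da:.6f},{sp.delta_mass_da:.6f}"
                f"  # {sp.composition.tag} {sp.loss.name}"
            )
    return "\n".join(lines) + "\n"


def _write_manifest(pfs: ParameterFileSet) -> None:
    with open(pfs.manifest_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for e in pfs.entries:
            fh.write(
                f"{e['group_id']}\t{e['delta_mass_da']:.6f}\t"
                f"{e['param_path']}\t"
                f"{'true' if e['light_only'] else 'false'}\t"
                f"{e['spectra_group']}\n"
            )


def generate_search_params(
    config: SearchConfig,
    groups: Sequence[SearchGroupDefinition],
    param_writer: Callable[..., str] = _default_param_writer,
) -> ParameterFileSet:
    """Write one parameter directory per search group plus a manifest.

    Regeneration over an existing tree is byte-identical for identical
    inputs.  Fails before writing anything on invalid config or an empty
    group list.
    """
    config.validate()
    if not groups:
        raise ValueError("empty group list")
    root = Path(config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    pfs = ParameterFileSet(root=root, manifest_path=root / "manifest.tsv")
    for group in groups:
        gdir = root / group.group_id
        gdir.mkdir(exist_ok=True)
        param_path = gdir / "params.txt"
        param_path.write_text(
            param_writer(config, group, False), encoding="utf-8"
        )
        pfs.entries.append(
            {
                "group_id": group.group_id,
                "delta_mass_da": group.delta_mass_da,
                "param_path": str(param_path.relative_to(root)),
                "light_only": False,
                "spectra_group": config.spectra_groups.get("default", ""),
            }
        )
    _write_manifest(pfs)
    return pfs


def generate_light_only_search(
    config: SearchConfig,
    pfs: ParameterFileSet,
    param_writer: Callable[..., str] = _default_param_writer,
) -> ParameterFileSet:
    """Append one light-only search (monolink mass 0, no pair requirement).

    The extra definition carries delta mass exactly 0 and is flagged
    ``light_only=true`` in the manifest.
    """
    config.validate()
    group = SearchGroupDefinition(
        group_id="light_only", delta_mass_da=0.0, members=[]
    )
    gdir = pfs.root / group.group_id
    gdir.mkdir(exist_ok=True)
    param_path = gdir / "params.txt"
    param_path.write_text(param_writer(config, group, True), encoding="utf-8")
    pfs.entries.append(
        {
            "group_id": group.group_id,
            "delta_mass_da": 0.0,
            "param_path": str(param_path.relative_to(pfs.root)),
            "light_only": True,
            "spectra_group": config.spectra_groups.get("default", ""),
        }
    )
    _write_manifest(pfs)
    return pfs


def read_manifest(path) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def make_decoy_db(
    fasta_in,
    fasta_out,
    mode: str = "reverse_then_shuffle",
    seed: int = 0,
    decoy_tag: str = "decoy_",
) -> int:
    """Write a decoy FASTA with one decoy record per target record.

    ``mode`` is one of reverse, shuffle, reverse_then_shuffle; shuffling
    is deterministic for a fixed seed, and sequence length and residue
    composition are always preserved.  Returns the number of decoy
    records written.
    """
    if mode not in ("reverse", "shuffle", "reverse_then_shuffle"):
        raise ValueError(f"unknown decoy mode: {mode!r}")
    rng = random.Random(seed)
    records = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_in), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"malformed FASTA record at index {i}: empty sequence")
        if mode in ("reverse", "reverse_then_shuffle"):
            seq = seq[::-1]
        if mode in ("shuffle", "reverse_then_shuffle"):
            chars = list(seq)
            rng.shuffle(chars)
            seq = "".join(chars)
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"{decoy_tag}{rec.id}",
                description="",
            )
        )
    if not records:
        logger.warning("input FASTA %s contained no records", fasta_in)
    SeqIO.write(records, str(fasta_out), "fasta")
    return len(records)
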