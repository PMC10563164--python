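"""Enumeration of RNA-derived peptide adducts and their isotope delta masses.

This module owns the chemistry bookkeeping of the pipeline: elemental
formulas with explicit heavy-isotope counts, nucleotide-composition
arithmetic, neutral-loss handling, isotope labeling schemes, and the
grouping of adduct species into parallel searches that share a single
expected light/heavy delta mass.

Conventions
-----------
* Oligonucleotide adducts default to a 5'-monophosphate / 3'-hydroxyl
  terminus (the mono-U adduct weighs 324.0359 Da).  A 5'-OH variant is
  available via ``terminus="5p_oh"`` (subtracts HPO3).
* An oligonucleotide of n residues is the sum of the member nucleotide
  5'-monophosphate formulas minus (n-1) waters.
* The cross-link linkage itself is zero-mass: the adduct contributes its
  full oligonucleotide mass (minus any neutral loss) to the peptide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "ElementalFormula",
    "NucleotideComposition",
    "LossSpec",
    "LabelingScheme",
    "AdductSpecies",
    "SearchGroupDefinition",
    "MONOISOTOPIC_MASS",
    "NUCLEOTIDE_MONOPHOSPHATE",
    "DEFAULT_LOSSES",
    "LOSS_BY_NAME",
    "LABELING_SCHEMES",
    "formula_mass",
    "enumerate_compositions",
    "build_adduct_species",
    "enumerate_adducts",
    "group_by_delta",
    "generate_covering_rna",
    "write_adduct_table",
    "read_adduct_table",
]

# Monoisotopic atomic masses (NIST); heavy isotopes listed under their
# conventional "<A><symbol>" tags.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "2H": 2.01410177785,
    "13C": 13.0033548378,
    "15N": 15.0001088982,
    "18O": 17.9991610,
}

#: isotope tag -> parent element symbol
_ISOTOPE_PARENT: Dict[str, str] = {"2H": "H", "13C": "C", "15N": "N", "18O": "O"}


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental formula with optional heavy-isotope substitutions.

    ``counts`` holds the *total* atom count per element (light + heavy);
    ``heavy`` holds, per isotope tag (e.g. ``"13C"``), how many of the
    parent element's atoms are the heavy isotope.  Arithmetic is exact on
    integers; subtraction that would go negative raises ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    heavy: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {e: int(n) for e, n in self.counts.items() if n != 0}
        heavy = {i: int(n) for i, n in self.heavy.items() if n != 0}
        for element, n in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element}: {n}")
        for isotope, n in heavy.items():
            parent = _ISOTOPE_PARENT.get(isotope)
            if parent is None:
                raise ValueError(f"unknown heavy isotope tag: {isotope!r}")
            if n < 0:
                raise ValueError(f"negative heavy count for {isotope}: {n}")
            if n > counts.get(parent, 0):
                raise ValueError(
                    f"heavy count {isotope}={n} exceeds {parent} count "
                    f"{counts.get(parent, 0)}"
                )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "heavy", heavy)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for e, n in other.counts.items():
            counts[e] = counts.get(e, 0) + n
        heavy = dict(self.heavy)
        for i, n in other.heavy.items():
            heavy[i] = heavy.get(i, 0) + n
        return ElementalFormula(counts, heavy)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for e, n in other.counts.items():
            new = counts.get(e, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for element {e}"
                )
            counts[e] = new
        heavy = dict(self.heavy)
        for i, n in other.heavy.items():
            new = heavy.get(i, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative heavy count for {i}"
                )
            heavy[i] = new
        return ElementalFormula(counts, heavy)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("formula multiplication requires k >= 0")
        return ElementalFormula(
            {e: n * k for e, n in self.counts.items()},
            {i: n * k for i, n in self.heavy.items()},
        )

    __rmul__ = __mul__

    def with_heavy(self, heavy: Mapping[str, int]) -> "ElementalFormula":
        """Return a copy with heavy-isotope counts replaced by ``heavy``."""
        return ElementalFormula(dict(self.counts), dict(heavy))

    @property
    def mass(self) -> float:
        return formula_mass(self)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-ish formula string like ``"C9H13N2O9P"``."""
        import re

        counts: Dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {pos}")
            pos = m.end()
            element = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[element] = counts.get(element, 0) + n
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {pos}")
        return cls(counts)

    def __str__(self) -> str:
        parts = []
        for e in sorted(self.counts):
            n = self.counts[e]
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts) or "(empty)"


def formula_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass of ``f`` in Da; heavy atoms use the heavy mass."""
    light = {e: n for e, n in f.counts.items()}
    total = 0.0
    for isotope, n in f.heavy.items():
        parent = _ISOTOPE_PARENT[isotope]
        light[parent] = light.get(parent, 0) - n
        total += n * MONOISOTOPIC_MASS[isotope]
    for element, n in light.items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {element!r}")
        total += n * MONOISOTOPIC_MASS[element]
    return total


_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True, order=True)
class NucleotideComposition:
    """Order-free base composition of an RNA oligonucleotide."""

    A: int = 0
    C: int = 0
    G: int = 0
    U: int = 0

    def __post_init__(self) -> None:
        for b in _BASES:
            if getattr(self, b) < 0:
                raise ValueError(f"negative count for base {b}")

    @property
    def length(self) -> int:
        return self.A + self.C + self.G + self.U

    @classmethod
    def from_sequence(cls, seq: str) -> "NucleotideComposition":
        seq = seq.upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in _BASES:
                raise ValueError(
                    f"invalid RNA base {ch!r} at position {pos}"
                )
        return cls(
            A=seq.count("A"), C=seq.count("C"),
            G=seq.count("G"), U=seq.count("U"),
        )

    @classmethod
    def from_tag(cls, tag: str) -> "NucleotideComposition":
        """Parse a compact tag such as ``"C1U2"`` or ``"U"``."""
        import re

        counts = {b: 0 for b in _BASES}
        pos = 0
        for m in re.finditer(r"([ACGU])(\d*)", tag):
            if m.start() != pos:
                raise ValueError(f"cannot parse composition tag {tag!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2)) if m.group(2) else 1
        if pos != len(tag) or pos == 0:
            raise ValueError(f"cannot parse composition tag {tag!r}")
        return cls(**counts)

    @property
    def tag(self) -> str:
        """Compact canonical form, e.g. ``"C1U1"``; bases in ACGU order."""
        parts = [f"{b}{getattr(self, b)}" for b in _BASES if getattr(self, b)]
        return "".join(parts)

    def counts(self) -> Dict[str, int]:
        return {b: getattr(self, b) for b in _BASES}

    def __str__(self) -> str:
        return self.tag


# Nucleotide 5'-monophosphate residue formulas (free acid).
NUCLEOTIDE_MONOPHOSPHATE: Dict[str, ElementalFormula] = {
    "A": ElementalFormula.parse("C10H14N5O7P"),
    "C": ElementalFormula.parse("C9H14N3O8P"),
    "G": ElementalFormula.parse("C10H14N5O8P"),
    "U": ElementalFormula.parse("C9H13N2O9P"),
}

_WATER = ElementalFormula.parse("H2O")
_HPO3 = ElementalFormula.parse("HPO3")


@dataclass(frozen=True)
class LossSpec:
    """A neutral loss applied to the oligonucleotide adduct."""

    name: str
    formula_delta: ElementalFormula

    def __str__(self) -> str:
        return self.name


DEFAULT_LOSSES: Tuple[LossSpec, ...] = (
    LossSpec("none", ElementalFormula()),
    LossSpec("-H2O", _WATER),
    LossSpec("-HPO3", _HPO3),
    LossSpec("-H3PO4", ElementalFormula.parse("H3PO4")),
)

LOSS_BY_NAME: Dict[str, LossSpec] = {l.name: l for l in DEFAULT_LOSSES}


@dataclass(frozen=True)
class LabelingScheme:
    """How heavy isotopes are distributed over an adduct.

    ``per_base`` maps each base to the heavy-isotope substitutions applied
    per residue of that base.  ``constant`` is applied once per adduct
    (used for the appended-phosphate 18O label); it is skipped when
    ``constant_requires`` names an element absent from the (post-loss)
    light formula, so a phosphate loss also removes the phosphate label.
    Substitution counts are clamped to the atoms actually present, which
    makes the delta mass reflect labeled atoms removed by a neutral loss.
    """

    name: str
    per_base: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    constant: Mapping[str, int] = field(default_factory=dict)
    constant_requires: str | None = None

    def heavy_counts(
        self, composition: NucleotideComposition, light: ElementalFormula
    ) -> Dict[str, int]:
        desired: Dict[str, int] = {}
        for base, subs in self.per_base.items():
            n_base = getattr(composition, base, 0)
            for isotope, k in subs.items():
                desired[isotope] = desired.get(isotope, 0) + k * n_base
        if self.constant and (
            self.constant_requires is None
            or light.counts.get(self.constant_requires, 0) > 0
        ):
            for isotope, k in self.constant.items():
                desired[isotope] = desired.get(isotope, 0) + k
        # clamp to available atoms so losses never make the formula invalid
        clamped: Dict[str, int] = {}
        for isotope, k in desired.items():
            avail = light.counts.get(_ISOTOPE_PARENT[isotope], 0)
            clamped[isotope] = min(k, avail)
        return clamped


LABELING_SCHEMES: Dict[str, LabelingScheme] = {
    "none": LabelingScheme("none"),
    # full 13C/15N metabolic labeling of the RNA
    "metabolic_13C15N": LabelingScheme(
        "metabolic_13C15N",
        per_base={
            "A": {"13C": 10, "15N": 5},
            "C": {"13C": 9, "15N": 3},
            "G": {"13C": 10, "15N": 5},
            "U": {"13C": 9, "15N": 2},
        },
    ),
    # 13C ribose only: five sugar carbons per residue
    "ribose_13C": LabelingScheme(
        "ribose_13C",
        per_base={b: {"13C": 5} for b in _BASES},
    ),
    # one 18O on the appended phosphate; vanishes with phosphate losses
    "phosphate_18O": LabelingScheme(
        "phosphate_18O", constant={"18O": 1}, constant_requires="P"
    ),
}


@dataclass(frozen=True)
class AdductSpecies:
    """One RNA-derived peptide modification with light and heavy forms."""

    composition: NucleotideComposition
    loss: LossSpec
    light_formula: ElementalFormula
    heavy_formula: ElementalFormula
    light_mass_da: float
    heavy_mass_da: float
    delta_mass_da: float
    scheme_name: str = "none"

    @property
    def tag(self) -> str:
        return f"{self.composition.tag}:{self.loss.name}"


@dataclass
class SearchGroupDefinition:
    """A parallel search: one delta mass plus the species sharing it."""

    group_id: str
    delta_mass_da: float
    members: List[AdductSpecies]
    settings: Dict[str, object] = field(default_factory=dict)


def enumerate_compositions(
    rna_sequence: str, min_len: int, max_len: int
) -> set:
    """Distinct base compositions of all contiguous substrings.

    Lengths ``min_len..max_len`` inclusive; compositions are order-free,
    so e.g. "CU" and "UC" windows collapse to one entry.
    """
    seq = rna_sequence.strip().upper()
    if not seq:
        raise ValueError("empty RNA sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _BASES:
            raise ValueError(f"invalid RNA base {ch!r} at position {pos}")
    if not (1 <= min_len <= max_len <= len(seq)):
        raise ValueError(
            f"require 1 <= min_len <= max_len <= len(sequence); got "
            f"min_len={min_len}, max_len={max_len}, len={len(seq)}"
        )
    out = set()
    for k in range(min_len, max_len + 1):
        for i in range(len(seq) - k + 1):
            out.add(NucleotideComposition.from_sequence(seq[i : i + k]))
    return out


def oligonucleotide_formula(
    composition: NucleotideComposition, terminus: str = "5p"
) -> ElementalFormula:
    """Light formula of the bare oligonucleotide (no loss applied)."""
    n = composition.length
    if n < 1:
        raise ValueError("composition must contain at least one nucleotide")
    total = ElementalFormula()
    for base, count in composition.counts().items():
        total = total + NUCLEOTIDE_MONOPHOSPHATE[base] * count
    total = total - _WATER * (n - 1)
    if terminus == "5p":
        pass
    elif terminus == "5p_oh":
        total = total - _HPO3
    else:
        raise ValueError(f"unknown terminus convention: {terminus!r}")
    return total


def build_adduct_species(
    composition: NucleotideComposition,
    loss: LossSpec,
    scheme: LabelingScheme | str,
    terminus: str = "5p",
) -> AdductSpecies:
    """Assemble one adduct species with light/heavy masses and delta."""
    if isinstance(scheme, str):
        scheme = LABELING_SCHEMES[scheme]
    base_formula = oligonucleotide_formula(composition, terminus=terminus)
    try:
        light = base_formula - loss.formula_delta
    except ValueError as exc:
        raise ValueError(
            f"loss {loss.name} not subtractable from {composition.tag}: {exc}"
        ) from exc
    heavy = light.with_heavy(scheme.heavy_counts(composition, light))
    light_mass = formula_mass(light)
    heavy_mass = formula_mass(heavy)
    return AdductSpecies(
        composition=composition,
        loss=loss,
        light_formula=light,
        heavy_formula=heavy,
        light_mass_da=light_mass,
        heavy_mass_da=heavy_mass,
        delta_mass_da=heavy_mass - light_mass,
        scheme_name=scheme.name,
    )


def enumerate_adducts(
    rna_sequence: str,
    scheme: LabelingScheme | str = "metabolic_13C15N",
    losses: Sequence[LossSpec] = DEFAULT_LOSSES,
    min_len: int = 1,
    max_len: int = 4,
    terminus: str = "5p",
) -> List[AdductSpecies]:
    """All (composition x loss) adduct species for an RNA sequence."""
    max_len = min(max_len, len(rna_sequence.strip()))
    comps = sorted(
        enumerate_compositions(rna_sequence, min_len, max_len),
        key=lambda c: (c.length, c.tag),
    )
    species = []
    for comp in comps:
        for loss in losses:
            species.append(
                build_adduct_species(comp, loss, scheme, terminus=terminus)
            )
    return species


def group_by_delta(
    species: Sequence[AdductSpecies], tol_da: float = 1e-4
) -> List[SearchGroupDefinition]:
    """Partition species into parallel-search groups by delta mass.

    Greedy single-linkage clustering on the sorted deltas; assignment is
    independent of input order because species are canonically sorted
    before clustering.  Group ids are ``g001, g002, ...`` in ascending
    delta order.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")
    ordered = sorted(
        species,
        key=lambda s: (s.delta_mass_da, s.composition.tag, s.loss.name),
    )
    groups: List[List[AdductSpecies]] = []
    for sp in ordered:
        if groups and abs(sp.delta_mass_da - groups[-1][0].delta_mass_da) <= tol_da:
            groups[-1].append(sp)
        else:
            groups.append([sp])
    out = []
    for i, members in enumerate(groups, start=1):
        out.append(
            SearchGroupDefinition(
                group_id=f"g{i:03d}",
                delta_mass_da=members[0].delta_mass_da,
                members=list(members),
            )
        )
    return out


def generate_covering_rna(
    k_max: int,
    alphabet: Iterable[str] = _BASES,
    method: str = "concat",
) -> str:
    """A sequence containing every base composition of lengths 1..k_max.

    ``method="concat"`` concatenates every sorted multiset of length
    ``k_max`` in lexicographic order.  Any shorter composition is a prefix
    of the sorted extension obtained by padding with its largest base, so
    coverage of all lengths 1..k_max follows.  For k_max=4 over ACGU this
    reproduces the 140-nt design sequence used for searches against
    arbitrary RNA.  ``method="greedy"`` grows a (usually shorter) sequence
    by appending whichever base covers the most remaining compositions.
    """
    bases = sorted(set(b.upper() for b in alphabet))
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not bases:
        raise ValueError("alphabet must be non-empty")

    if method == "concat":
        chunks = [
            "".join(combo)
            for combo in itertools.combinations_with_replacement(bases, k_max)
        ]
        return "".join(chunks)

    if method != "greedy":
        raise ValueError(f"unknown method: {method!r}")

    def comps_of(seq: str) -> set:
        found = set()
        for k in range(1, k_max + 1):
            for i in range(len(seq) - k + 1):
                found.add(tuple(sorted(seq[i : i + k])))
        return found

    target = set()
    for k in range(1, k_max + 1):
        target.update(itertools.combinations_with_replacement(bases, k))

    seq = ""
    uncovered = set(target)
    while uncovered:
        best_base, best_gain = None, -1
        for b in bases:
            cand = seq + b
            gain = len(
                uncovered
                & {
                    tuple(sorted(cand[max(0, len(cand) - k):]))
                    for k in range(1, k_max + 1)
                }
            )
            if gain > best_gain:
                best_base, best_gain = b, gain
        if best_gain > 0:
            seq += best_base
        else:
            # stalled: splice in the smallest uncovered multiset verbatim
            seq += "".join(min(uncovered))
        uncovered = target - comps_of(seq)
    return seq


# ---------------------------------------------------------------------------
# serialization

ADDUCT_TABLE_COLUMNS = (
    "composition",
    "loss",
    "light_mass_da",
    "heavy_mass_da",
    "delta_mass_da",
    "group_id",
)


def write_adduct_table(groups: Sequence[SearchGroupDefinition], path) -> None:
    """Serialize grouped adduct species as TSV (masses at 6 dp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ADDUCT_TABLE_COLUMNS) + "\n")
        for g in groups:
            for sp in g.members:
                fh.write(
                    "\t".join(
                        [
                            sp.composition.tag,
                            sp.loss.name,
                            f"{sp.light_mass_da:.6f}",
                            f"{sp.heavy_mass_da:.6f}",
                            f"{sp.delta_mass_da:.6f}",
                            g.group_id,
                        ]
                    )
                    + "\n"
                )


def read_adduct_table(path) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(ADDUCT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"adduct table missing columns: {sorted(missing)}")
    return df
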