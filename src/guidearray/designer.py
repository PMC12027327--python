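"""Design of spacer oligos and position-specific Type IIS primer sets.

A gRNA unit is built by polymerase cycling assembly (PCA) from a dsDNA U6
promoter fragment, a single-stranded spacer oligo bridging promoter and
scaffold, and a dsDNA scaffold/terminator fragment.  A position-specific
primer pair then amplifies the unit while adding BsaI tails whose 4-nt
overhangs encode the unit's slot in the array, so that one-pot Golden Gate
digestion/ligation can only assemble the units in the designed order.

Layout of one amplified unit (top strand)::

    [TT GGTCTC A <left-overhang>] [U6] [spacer] [scaffold] [<right-overhang>' T GAGACC AA]

The bracketed tails are contributed by the primers; BsaI cuts just inside
them, releasing a unit core flanked by the two junction overhangs.  With
the bundled reference lengths (U6 250 nt, scaffold 137 nt, 13-nt tails)
the amplicon is 433 bp and a 20-nt spacer needs a single 59-nt oligo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dna import (
    BSAI_SITES,
    BSMBI_SITES,
    find_sites,
    has_sites,
    is_dna,
    normalize,
    revcomp,
)
from .overhangs import OverhangSet, default_overhang_set, validate_overhang_set

__all__ = [
    "ReferenceSet",
    "SpacerOligo",
    "PositionPrimerPair",
    "GRNAUnit",
    "ArrayDesign",
    "validate_spacer",
    "design_spacer_oligo",
    "design_position_primers",
    "design_array",
    "predicted_unit",
    "ligated_unit",
    "export_order_sheet",
    "default_reference_set",
    "PRIMER_PAD",
    "BSAI_RECOGNITION",
    "SPACER_BASE",
    "TAIL_LEN",
]

#: 5' pad ahead of the recognition site, for efficient digestion near ends.
PRIMER_PAD = "TT"
BSAI_RECOGNITION = "GGTCTC"
#: single base between recognition site and the 4-nt overhang (BsaI N1 geometry)
SPACER_BASE = "A"
#: pad + recognition + spacer base + overhang
TAIL_LEN = len(PRIMER_PAD) + len(BSAI_RECOGNITION) + len(SPACER_BASE) + 4

MIN_ARM_LEN = 12
SPACER_LEN_RANGE = (18, 25)

REGION_ORDER = ("fwd_primer_region", "u6", "spacer", "scaffold", "rev_primer_region")


@dataclass(frozen=True)
class ReferenceSet:
    """Sequences and annealing geometry everything is designed against.

    ``u6`` and ``scaffold`` are the PCA building blocks; ``vector_backbone``
    is the destination-vector backbone (everything that remains in the final
    plasmid outside the Golden Gate cut sites).  Arm lengths set the spacer
    oligo's homology to the U6 3' end and the scaffold 5' end; anneal
    lengths set the primer footprints.
    """

    u6: str
    scaffold: str
    vector_backbone: str
    fwd_anneal_len: int = 20
    rev_anneal_len: int = 20
    up_arm_len: int = 20
    down_arm_len: int = 19

    def __post_init__(self):
        object.__setattr__(self, "u6", normalize(self.u6))
        object.__setattr__(self, "scaffold", normalize(self.scaffold))
        object.__setattr__(self, "vector_backbone", normalize(self.vector_backbone))
        for name in ("u6", "scaffold", "vector_backbone"):
            seq = getattr(self, name)
            if not seq or not is_dna(seq):
                raise ValueError(f"{name} must be a non-empty ACGT sequence")
            if has_sites(seq, BSAI_SITES):
                raise ValueError(f"{name} contains a BsaI recognition site")
        for name in ("up_arm_len", "down_arm_len"):
            if getattr(self, name) < MIN_ARM_LEN:
                raise ValueError(f"{name} below minimum assembly homology "
                                 f"({MIN_ARM_LEN} nt)")
        if self.fwd_anneal_len > len(self.u6):
            raise ValueError("fwd_anneal_len exceeds u6 length")
        if self.rev_anneal_len > len(self.scaffold):
            raise ValueError("rev_anneal_len exceeds scaffold length")

    @property
    def unit_length_for(self) -> int:
        """Amplicon length for a 20-nt spacer (tails + U6 + spacer + scaffold)."""
        return 2 * TAIL_LEN + len(self.u6) + 20 + len(self.scaffold)

    @classmethod
    def from_fasta(cls, path: str | Path, **geometry) -> "ReferenceSet":
        """Load from a multi-FASTA with record ids U6, SCAFFOLD and VECTOR."""
        from .io import read_fasta

        records = {name.upper(): seq for name, seq in read_fasta(path)}
        missing = {"U6", "SCAFFOLD", "VECTOR"} - records.keys()
        if missing:
            raise ValueError(f"{path}: missing reference records {sorted(missing)}")
        return cls(
            u6=records["U6"],
            scaffold=records["SCAFFOLD"],
            vector_backbone=records["VECTOR"],
            **geometry,
        )

    def to_fasta(self, path: str | Path) -> None:
        from .io import write_fasta

        write_fasta(
            path,
            [("U6", self.u6), ("SCAFFOLD", self.scaffold),
             ("VECTOR", self.vector_backbone)],
        )


@dataclass(frozen=True)
class SpacerOligo:
    """Single-stranded bridging oligo: U6 3' arm + spacer + scaffold 5' arm."""

    name: str
    position: int
    spacer: str
    sequence: str


@dataclass(frozen=True)
class PositionPrimerPair:
    """BsaI-tailed amplification primers encoding one array slot."""

    position: int
    fwd: str
    rev: str
    left_overhang: str
    right_overhang: str


@dataclass(frozen=True)
class GRNAUnit:
    """A unit sequence with its region annotation.

    ``regions`` maps each of fwd_primer_region / u6 / spacer / scaffold /
    rev_primer_region to a 0-based half-open interval; the intervals tile
    the sequence in that order.  Primer regions cover the full primer
    footprints (tails plus annealing stretches).
    """

    sequence: str
    regions: dict[str, tuple[int, int]]

    def __post_init__(self):
        pos = 0
        for label in REGION_ORDER:
            start, end = self.regions[label]
            if start != pos or end < start:
                raise ValueError(f"region {label} does not tile the sequence")
            pos = end
        if pos != len(self.sequence):
            raise ValueError("regions do not cover the full sequence")

    def region_seq(self, label: str) -> str:
        start, end = self.regions[label]
        return self.sequence[start:end]


@dataclass
class ArrayDesign:
    """Complete design artifact for one ordered gRNA array."""

    k: int
    spacers: list[str]
    names: list[str]
    overhangs: OverhangSet  # the k+1 junctions actually used, in order
    refs: ReferenceSet
    primer_pairs: list[PositionPrimerPair]
    spacer_oligos: list[SpacerOligo]
    predicted_units: list[GRNAUnit]
    predicted_insert: str
    predicted_plasmid: str

    @property
    def unit_core_length(self) -> int:
        """Per-unit period inside the ligated insert (overhang + U6+spacer+scaffold).

        This is what read-length binning divides by; the primer tails
        outside the BsaI cuts are gone from the ligated insert.
        """
        lens = {len(s) for s in self.spacers}
        if len(lens) != 1:
            raise ValueError("spacers of mixed length have no single unit period")
        return 4 + len(self.refs.u6) + lens.pop() + len(self.refs.scaffold)


def validate_spacer(spacer: str, refs: ReferenceSet) -> list[str]:
    """Report problems with a spacer; ``warning:``-prefixed entries are soft.

    Hard violations: non-ACGT characters, or a BsaI/BsmBI recognition site
    anywhere in the assembled oligo context (spacer plus both homology
    arms — a site spanning a junction is just as destructive).  BsaI would
    corrupt the Golden Gate reaction, BsmBI the clone-screening digest.
    Length outside 18-25 nt is flagged as a warning only.
    """
    spacer = normalize(spacer)
    violations: list[str] = []
    if not spacer:
        violations.append("spacer is empty")
        return violations
    if not is_dna(spacer):
        violations.append(f"spacer contains non-ACGT characters: {spacer!r}")
        return violations
    lo, hi = SPACER_LEN_RANGE
    if not lo <= len(spacer) <= hi:
        violations.append(
            f"warning: spacer length {len(spacer)} outside typical range "
            f"[{lo},{hi}]"
        )
    context = refs.u6[-refs.up_arm_len:] + spacer + refs.scaffold[: refs.down_arm_len]
    for start, motif in find_sites(context, BSAI_SITES + BSMBI_SITES):
        enzyme = "BsaI" if motif in BSAI_SITES else "BsmBI"
        violations.append(
            f"{enzyme} site ({motif}) at offset {start} of the assembled "
            f"oligo context"
        )
    return violations


def hard_violations(violations: list[str]) -> list[str]:
    return [v for v in violations if not v.startswith("warning:")]


def design_spacer_oligo(
    spacer: str, position: int, refs: ReferenceSet, name: str | None = None
) -> SpacerOligo:
    """Build the single-stranded bridging oligo for one spacer.

    The oligo is the last ``up_arm_len`` nt of U6, the spacer, then the
    first ``down_arm_len`` nt of the scaffold — 59 nt for a 20-nt spacer
    under the default 20/19 arms.
    """
    spacer = normalize(spacer)
    bad = hard_violations(validate_spacer(spacer, refs))
    if bad:
        raise ValueError(f"spacer {name or spacer!r} invalid: {'; '.join(bad)}")
    seq = refs.u6[-refs.up_arm_len:] + spacer + refs.scaffold[: refs.down_arm_len]
    return SpacerOligo(
        name=name or f"spacer_{position}",
        position=position,
        spacer=spacer,
        sequence=seq,
    )


def design_position_primers(
    position: int, overhangs: OverhangSet, refs: ReferenceSet
) -> PositionPrimerPair:
    """Primer pair for one array slot.

    ``overhangs`` is the design's junction set (k+1 entries); slot p uses
    junction p-1 on its left and junction p on its right.  Adjacent slots
    therefore share exactly one junction, which is what enforces the
    assembly order.
    """
    if not 1 <= position <= len(overhangs) - 1:
        raise ValueError(
            f"position {position} out of range 1..{len(overhangs) - 1} for a "
            f"{len(overhangs)}-junction overhang set"
        )
    left = overhangs[position - 1]
    right = overhangs[position]
    fwd = (PRIMER_PAD + BSAI_RECOGNITION + SPACER_BASE + left
           + refs.u6[: refs.fwd_anneal_len])
    rev = (PRIMER_PAD + BSAI_RECOGNITION + SPACER_BASE + revcomp(right)
           + revcomp(refs.scaffold[-refs.rev_anneal_len:]))
    for strand, primer in (("fwd", fwd), ("rev", rev)):
        n_sites = len(find_sites(primer, BSAI_SITES))
        if n_sites != 1:
            raise ValueError(
                f"{strand} primer for position {position} carries {n_sites} "
                f"BsaI sites (expected exactly 1); junction overhang or "
                f"reference terminus creates a spurious site"
            )
    return PositionPrimerPair(
        position=position, fwd=fwd, rev=rev, left_overhang=left,
        right_overhang=right,
    )


def _amplicon(spacer: str, pair: PositionPrimerPair, refs: ReferenceSet) -> str:
    fwd_tail = pair.fwd[: -refs.fwd_anneal_len]
    rev_tail = pair.rev[: -refs.rev_anneal_len]
    return fwd_tail + refs.u6 + spacer + refs.scaffold + revcomp(rev_tail)


def _unit_regions(spacer_len: int, refs: ReferenceSet) -> dict[str, tuple[int, int]]:
    fwd_end = TAIL_LEN + refs.fwd_anneal_len
    u6_end = TAIL_LEN + len(refs.u6)
    sp_end = u6_end + spacer_len
    sc_end = sp_end + len(refs.scaffold)
    return {
        "fwd_primer_region": (0, fwd_end),
        "u6": (fwd_end, u6_end),
        "spacer": (u6_end, sp_end),
        "scaffold": (sp_end, sc_end - refs.rev_anneal_len),
        "rev_primer_region": (sc_end - refs.rev_anneal_len, sc_end + TAIL_LEN),
    }


def predicted_unit(position: int, design: "ArrayDesign") -> GRNAUnit:
    """The full PCA amplicon for one slot, with its region annotation."""
    if not 1 <= position <= design.k:
        raise ValueError(f"position {position} out of range 1..{design.k}")
    return design.predicted_units[position - 1]


def ligated_unit(position: int, design: "ArrayDesign") -> GRNAUnit:
    """The unit as it appears inside the ligated insert.

    BsaI digestion removes the primer tails; what each unit contributes to
    the insert is its left junction overhang plus the U6+spacer+scaffold
    core.  Primer annealing stretches (the overhang plus the U6 5' and
    scaffold 3' footprints) are still annotated as primer regions so that
    mutation classification can ignore them.
    """
    refs = design.refs
    spacer = design.spacers[position - 1]
    left = design.overhangs[position - 1]
    seq = left + refs.u6 + spacer + refs.scaffold
    fwd_end = 4 + refs.fwd_anneal_len
    u6_end = 4 + len(refs.u6)
    sp_end = u6_end + len(spacer)
    sc_end = sp_end + len(refs.scaffold)
    regions = {
        "fwd_primer_region": (0, fwd_end),
        "u6": (fwd_end, u6_end),
        "spacer": (u6_end, sp_end),
        "scaffold": (sp_end, sc_end - refs.rev_anneal_len),
        "rev_primer_region": (sc_end - refs.rev_anneal_len, sc_end),
    }
    return GRNAUnit(sequence=seq, regions=regions)


def predicted_insert_for(design: "ArrayDesign", unit_count: int | None = None) -> str:
    """Expected insert sequence for the first ``unit_count`` units.

    The insert runs junction0 + core1 + junction1 + ... + core_j +
    terminal junction; the terminal junction is always the vector-side
    one, whatever j is (truncated assemblies still close onto the vector).
    """
    j = design.k if unit_count is None else unit_count
    if not 1 <= j <= design.k:
        raise ValueError(f"unit_count {j} out of range 1..{design.k}")
    parts = []
    for i in range(j):
        parts.append(design.overhangs[i])
        parts.append(design.refs.u6 + design.spacers[i] + design.refs.scaffold)
    parts.append(design.overhangs[-1])
    return "".join(parts)


def design_array(
    spacers: list[str],
    refs: ReferenceSet | None = None,
    overhangs: OverhangSet | None = None,
    names: list[str] | None = None,
) -> ArrayDesign:
    """Turn an ordered spacer list into a complete array design.

    ``overhangs`` may be a capacity set larger than needed; slot p then uses
    junction p-1 on the left, and the set's *last* element is always the
    terminal (unit_k -> vector) junction so the destination vector's two
    overhangs do not depend on k.
    """
    if refs is None:
        refs = default_reference_set()
    if overhangs is None:
        overhangs = default_overhang_set()
    k = len(spacers)
    if k < 1:
        raise ValueError("need at least one spacer")
    if k > overhangs.max_units:
        raise ValueError(
            f"{k} units exceed this overhang set's capacity of "
            f"{overhangs.max_units} units ({len(overhangs)} junctions)"
        )
    bad = validate_overhang_set(overhangs)
    if bad:
        raise ValueError(f"overhang set invalid: {bad}")
    spacers = [normalize(s) for s in spacers]
    names = list(names) if names else [f"g{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names and spacers differ in length")

    used = OverhangSet(tuple(list(overhangs)[:k] + [overhangs[-1]]))
    oligos = [
        design_spacer_oligo(s, i + 1, refs, name=names[i])
        for i, s in enumerate(spacers)
    ]
    pairs = [design_position_primers(p, used, refs) for p in range(1, k + 1)]
    units = [
        GRNAUnit(
            sequence=_amplicon(spacers[i], pairs[i], refs),
            regions=_unit_regions(len(spacers[i]), refs),
        )
        for i in range(k)
    ]
    for i, unit in enumerate(units):
        sites = find_sites(unit.sequence, BSAI_SITES)
        if len(sites) != 2:
            raise ValueError(
                f"predicted unit {i + 1} carries {len(sites)} BsaI sites "
                f"(expected the 2 primer-tail sites)"
            )
    design = ArrayDesign(
        k=k,
        spacers=spacers,
        names=names,
        overhangs=used,
        refs=refs,
        primer_pairs=pairs,
        spacer_oligos=oligos,
        predicted_units=units,
        predicted_insert="",
        predicted_plasmid="",
    )
    design.predicted_insert = predicted_insert_for(design)
    design.predicted_plasmid = refs.vector_backbone + design.predicted_insert
    return design


def export_order_sheet(design: ArrayDesign) -> pd.DataFrame:
    """One row per oligo to order: k spacer oligos plus 2k primers."""
    rows = []
    for oligo in design.spacer_oligos:
        rows.append(
            dict(name=oligo.name + "_oligo", sequence=oligo.sequence,
                 length=len(oligo.sequence), position=oligo.position,
                 role="spacer_oligo")
        )
    for pair in design.primer_pairs:
        rows.append(
            dict(name=f"pos{pair.position}_fwd", sequence=pair.fwd,
                 length=len(pair.fwd), position=pair.position,
                 role="fwd_primer")
        )
        rows.append(
            dict(name=f"pos{pair.position}_rev", sequence=pair.rev,
                 length=len(pair.rev), position=pair.position,
                 role="rev_primer")
        )
    return pd.DataFrame(rows, columns=["name", "sequence", "length",
                                       "position", "role"])


_DEFAULT_REFS: ReferenceSet | None = None


def default_reference_set() -> ReferenceSet:
    """Bundled synthetic reference set (deterministic).

    Stand-in sequences with realistic lengths (U6 promoter 250 nt, scaffold
    + terminator 137 nt, backbone 2200 nt), generated free of BsaI/BsmBI
    sites so that the predicted amplicon for a 20-nt spacer is 433 bp.
    Real MLM3636-derived sequences can be supplied via FASTA instead.
    """
    global _DEFAULT_REFS
    if _DEFAULT_REFS is None:
        from .simreads import make_reference_set

        _DEFAULT_REFS = make_reference_set(seed=7)
    return _DEFAULT_REFS
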