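"""Synthetic fixtures: reference sets, clone populations and noisy long reads.

The generator emulates the two sequencing experiments the read-QC stack
must analyze: bulk whole-plasmid nanopore sequencing of a transformation
pool (mixed full-length and truncated assemblies) and per-clone plasmid
sequencing (multiple reads of one clone).  Clone plasmids carry injected
mutations at a controlled per-unit rate; reads are random rotations of
the circular plasmid, on either strand, with i.i.d. per-base
substitution/insertion/deletion noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import designer
from .designer import ArrayDesign, ReferenceSet, ligated_unit, predicted_insert_for
from .dna import BSAI_SITES, BSMBI_SITES, has_sites, revcomp

__all__ = [
    "ReadSimConfig",
    "CloneTruth",
    "make_reference_set",
    "simulate_clone_population",
    "simulate_reads",
    "random_spacer",
]

_ALL_SITES = BSAI_SITES + BSMBI_SITES
_BASES = np.frombuffer(b"ACGT", dtype="S1")

CONSEQUENTIAL_REGIONS = ("u6", "spacer", "scaffold")


def _random_clean_seq(rng: np.random.Generator, length: int,
                      max_attempts: int = 10_000) -> str:
    """Random ACGT sequence free of BsaI/BsmBI sites on both strands."""
    for _ in range(max_attempts):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not has_sites(seq, _ALL_SITES):
            return seq
    raise RuntimeError(
        f"could not sample a {length}-nt enzyme-site-free sequence in "
        f"{max_attempts} attempts"
    )


def random_spacer(rng: np.random.Generator, length: int = 20) -> str:
    """A random spacer whose assembled oligo context is enzyme-site-free."""
    refs = designer.default_reference_set()
    for _ in range(1000):
        sp = "".join(rng.choice(list("ACGT"), size=length))
        if not designer.hard_violations(designer.validate_spacer(sp, refs)):
            return sp
    raise RuntimeError("could not sample a clean spacer")


def make_reference_set(
    seed: int,
    u6_len: int = 250,
    scaffold_len: int = 137,
    backbone_len: int = 2200,
    fwd_anneal_len: int = 20,
    rev_anneal_len: int = 20,
    up_arm_len: int = 20,
    down_arm_len: int = 19,
) -> ReferenceSet:
    """Deterministic synthetic reference set.

    Sequences are rejection-sampled free of BsaI and BsmBI sites on both
    strands.  The default lengths give a 433-bp amplicon for a 20-nt
    spacer (13-nt primer tails on each side) and a 59-nt spacer oligo
    (20/19 homology arms).  The outer seed is also advanced until the
    references are compatible with the bundled default overhang set (no
    junction-spanning enzyme site in any of the 20 position primers).
    """
    for attempt in range(50):
        rng = np.random.default_rng([seed, attempt])
        try:
            refs = ReferenceSet(
                u6=_random_clean_seq(rng, u6_len),
                scaffold=_random_clean_seq(rng, scaffold_len),
                vector_backbone=_random_clean_seq(rng, backbone_len),
                fwd_anneal_len=fwd_anneal_len,
                rev_anneal_len=rev_anneal_len,
                up_arm_len=up_arm_len,
                down_arm_len=down_arm_len,
            )
            _probe_design(refs, rng)
            return refs
        except ValueError:
            continue
    raise RuntimeError("could not build a usable reference set")


def _probe_design(refs: ReferenceSet, rng: np.random.Generator) -> None:
    """Raise if a full-capacity design against ``refs`` is not clean."""
    from .overhangs import default_overhang_set

    ohset = default_overhang_set()
    spacers = []
    while len(spacers) < ohset.max_units:
        sp = "".join(rng.choice(list("ACGT"), size=20))
        if not designer.hard_violations(designer.validate_spacer(sp, refs)):
            spacers.append(sp)
    designer.design_array(spacers, refs, ohset)


@dataclass
class ReadSimConfig:
    """Study conditions for one simulated sequencing experiment.

    Defaults mirror the characterized system: 10-unit arrays with an 81%
    full-length fraction, a 7.5% per-unit consequential mutation rate, and
    long-read noise at a polished-nanopore-like 0.5% per-base
    substitution plus 0.25% insertion and 0.25% deletion rates (raise
    these for raw-read emulation).
    """

    n_reads: int = 1000
    full_length_fraction: float = 0.81
    truncation_model: dict[int, float] | None = None  # unit_count -> weight
    per_unit_consequential_rate: float = 0.075
    primer_region_rate: float = 0.0
    sub_rate: float = 0.005
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    #: named spacer pool (gRNA id -> spacer sequence) for library mode
    pool: dict[str, str] | None = None
    #: per-position restriction: position -> allowed gRNA ids (default: all)
    pool_per_position: dict[int, list[str]] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("full_length_fraction", "per_unit_consequential_rate",
                     "primer_region_rate", "sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if getattr(self, name) >= 0.2:
                raise ValueError(f"{name} too high for a meaningful read model")
        if self.truncation_model is not None:
            if any(w < 0 for w in self.truncation_model.values()):
                raise ValueError("truncation weights must be non-negative")


@dataclass
class CloneTruth:
    """Ground truth for one simulated clone."""

    clone_id: str
    unit_count: int
    spacer_ids: list[str]            # per position, length unit_count
    mutated_units: list[int]         # 1-based positions with a consequential edit
    mutations: list[dict] = field(default_factory=list)


def _inject_edit(seq: str, start: int, end: int, rng: np.random.Generator,
                 ) -> tuple[str, dict]:
    """One random substitution/insertion/deletion uniformly inside [start,end)."""
    kind = ("substitution", "insertion", "deletion")[rng.integers(3)]
    pos = int(rng.integers(start, end))
    if kind == "substitution":
        alt = rng.choice([b for b in "ACGT" if b != seq[pos]])
        new = seq[:pos] + alt + seq[pos + 1:]
        rec = dict(kind=kind, offset=pos, ref=seq[pos], alt=alt)
    elif kind == "insertion":
        alt = rng.choice(list("ACGT"))
        new = seq[:pos] + alt + seq[pos:]
        rec = dict(kind=kind, offset=pos, ref="", alt=alt)
    else:
        new = seq[:pos] + seq[pos + 1:]
        rec = dict(kind=kind, offset=pos, ref=seq[pos], alt="")
    return new, rec


def simulate_clone_population(
    design: ArrayDesign, config: ReadSimConfig, n_clones: int | None = None
) -> list[tuple[str, CloneTruth]]:
    """Draw a clone population with controlled composition.

    Each clone is full length with probability ``full_length_fraction``,
    otherwise its unit count is drawn from ``truncation_model`` (default:
    uniform over 1..k-1).  With ``pool_per_position`` set, every unit's
    spacer is drawn uniformly from that position's pool.  Each unit then
    receives one consequential edit (uniform over its U6+spacer+scaffold
    span) with probability ``per_unit_consequential_rate``, and one
    primer-region edit with probability ``primer_region_rate``.

    Returns (plasmid sequence, truth) pairs; plasmids are linear strings
    with origin at the vector backbone start.
    """
    rng = np.random.default_rng(config.seed)
    k = design.k
    if n_clones is None:
        n_clones = config.n_reads
    trunc = config.truncation_model
    if trunc is None:
        trunc = {j: 1.0 for j in range(1, k)} if k > 1 else {k: 1.0}
    tr_counts = sorted(trunc)
    tr_w = np.array([trunc[j] for j in tr_counts], dtype=float)
    if tr_w.sum() == 0:
        raise ValueError("truncation model has zero total weight")
    tr_w = tr_w / tr_w.sum()
    pool = config.pool
    per_position = config.pool_per_position
    if pool is not None and per_position is None:
        per_position = {p: sorted(pool) for p in range(1, k + 1)}

    clones = []
    for c in range(n_clones):
        if rng.random() < config.full_length_fraction:
            j = k
        else:
            j = int(tr_counts[rng.choice(len(tr_counts), p=tr_w)])
        if pool is not None:
            ids = [
                per_position[pos][int(rng.integers(len(per_position[pos])))]
                for pos in range(1, j + 1)
            ]
            spacers = [pool[i] for i in ids]
        else:
            spacers = design.spacers[:j]
            ids = design.names[:j]

        truth = CloneTruth(
            clone_id=f"clone{c}", unit_count=j, spacer_ids=ids, mutated_units=[]
        )
        insert_parts = []
        for pos in range(1, j + 1):
            unit = ligated_unit(pos, design)
            seq = design.overhangs[pos - 1] + design.refs.u6 + spacers[pos - 1] \
                + design.refs.scaffold
            regions = dict(unit.regions)
            if len(spacers[pos - 1]) != len(design.spacers[pos - 1]):
                raise ValueError("pool spacers must match the design length")
            if rng.random() < config.per_unit_consequential_rate:
                lo = regions["u6"][0]
                hi = regions["scaffold"][1]
                seq, rec = _inject_edit(seq, lo, hi, rng)
                rec.update(unit_position=pos, consequential=True)
                truth.mutations.append(rec)
                truth.mutated_units.append(pos)
            if rng.random() < config.primer_region_rate:
                lo, hi = regions["fwd_primer_region"]
                seq, rec = _inject_edit(seq, lo, hi, rng)
                rec.update(unit_position=pos, consequential=False)
                truth.mutations.append(rec)
            insert_parts.append(seq)
        insert = "".join(insert_parts) + design.overhangs[-1]
        plasmid = design.refs.vector_backbone + insert
        clones.append((plasmid, truth))
    return clones


def _noisy_read(seq: str, rng: np.random.Generator, sub: float, ins: float,
                dl: float) -> str:
    """Apply i.i.d. per-base noise (vectorized)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    u = rng.random(n)
    keep = u >= dl
    arr = arr[keep]
    n = len(arr)
    subs = rng.random(n) < sub
    if subs.any():
        arr = arr.copy()
        # shift by 1..3 in base space => always a different base
        idx = np.searchsorted(_BASES, arr[subs])
        arr[subs] = _BASES[(idx + rng.integers(1, 4, subs.sum())) % 4]
    ins_mask = rng.random(n + 1) < ins
    if ins_mask.any():
        out = []
        positions = np.flatnonzero(ins_mask)
        prev = 0
        for p in positions:
            out.append(arr[prev:p])
            out.append(_BASES[rng.integers(4, size=1)])
            prev = p
        out.append(arr[prev:])
        arr = np.concatenate(out)
    return arr.tobytes().decode()


def simulate_reads(
    plasmids: list[tuple[str, CloneTruth]],
    config: ReadSimConfig,
    n_reads: int | None = None,
    per_clone: int | None = None,
) -> tuple[list[tuple[str, str, str]], list[dict]]:
    """Whole-plasmid long reads from a clone population.

    Each read picks a clone uniformly (or, with ``per_clone``, exactly that
    many reads per clone in clone order — the bulk-sequencing assumption
    that each read stems from an individual clone, and the per-clone
    sequencing layout), rotates the circular plasmid to a random origin,
    picks a strand uniformly, then applies per-base noise.  Returns
    (records, truth_table): records are (read_id, sequence, quality) FASTQ
    triples with a constant placeholder quality; the truth table links
    read_id to clone_id, strand and rotation.
    """
    rng = np.random.default_rng([config.seed, 1])
    if per_clone is not None:
        clone_order = [c for c in range(len(plasmids)) for _ in range(per_clone)]
        n_reads = len(clone_order)
    else:
        clone_order = None
        if n_reads is None:
            n_reads = config.n_reads
    records, truth = [], []
    for r in range(n_reads):
        ci = clone_order[r] if clone_order else int(rng.integers(len(plasmids)))
        plasmid, clone = plasmids[ci]
        origin = int(rng.integers(len(plasmid)))
        rotated = plasmid[origin:] + plasmid[:origin]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            rotated = revcomp(rotated)
        read = _noisy_read(rotated, rng, config.sub_rate, config.ins_rate,
                           config.del_rate)
        rid = f"read{r}"
        records.append((rid, read, "I" * len(read)))
        truth.append(
            dict(read_id=rid, clone_id=clone.clone_id, strand=strand,
                 origin=origin, unit_count=clone.unit_count,
                 spacer_ids=",".join(clone.spacer_ids),
                 mutated_units=",".join(map(str, clone.mutated_units)))
        )
    return records, truth
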