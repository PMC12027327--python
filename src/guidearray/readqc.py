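"""Nanopore whole-plasmid read QC for assembled gRNA arrays.

The analysis chain mirrors how pooled-transformant plasmid sequencing is
evaluated: locate the array insert between known backbone flanking
sequences (approximate, either strand, origin-wrapping reads handled by
searching the doubled read), bin the insert length into a unit count,
split the insert into per-position units by alignment to the designed
insert, identify each unit's gRNA by normalized edit-distance similarity
against the spacer pool, and classify per-unit mutations by the region
they fall in.  Edits inside the PCA primer footprints are recorded but
flagged non-consequential; only U6/spacer/scaffold edits count toward the
per-unit mutation rate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .designer import ArrayDesign, GRNAUnit, predicted_insert_for
from .dna import normalize, revcomp

__all__ = [
    "InsertCall",
    "MutationCall",
    "PositionAbundanceMatrix",
    "SegmentationError",
    "extract_insert",
    "bin_unit_count",
    "assembly_efficiency",
    "full_length_fraction",
    "segment_units",
    "consensus_insert",
    "assign_grna",
    "extract_spacer",
    "similarity",
    "abundance_matrix",
    "classify_mutations",
    "mutation_rate",
    "clone_mutation_calls",
    "analyze_reads",
]

MIN_FLANK_LEN = 15
CONSEQUENTIAL_REGIONS = frozenset({"u6", "spacer", "scaffold"})


class SegmentationError(ValueError):
    """Insert could not be aligned to the designed insert."""


@dataclass
class MutationCall:
    unit_position: int
    region: str
    kind: str  # substitution | insertion | deletion
    offset: int  # 0-based within the expected unit
    ref: str
    alt: str
    consequential: bool = field(init=False)

    def __post_init__(self):
        self.consequential = self.region in CONSEQUENTIAL_REGIONS


@dataclass
class InsertCall:
    """Per-read QC result."""

    read_id: str
    strand: str | None = None
    insert: str | None = None
    unit_count: int | None = None
    assignments: list[tuple[str, float]] | None = None
    mutations: list[MutationCall] | None = None
    segmentation_ok: bool = True

    @property
    def insert_length(self) -> int:
        return len(self.insert) if self.insert else 0


def _best_hit(query: str, target: str, max_dist: int):
    """Best approximate infix occurrence; (start, end) or None."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return (0 if start is None else start), end + 1


def extract_insert(
    read: str,
    flank_up: str,
    flank_down: str,
    max_edit_frac: float = 0.2,
    circular: bool = True,
    read_id: str = "read",
) -> InsertCall:
    """Locate the array insert between two backbone flanks.

    Both the read and its reverse complement are searched; with
    ``circular`` (the default — whole-plasmid reads start at an arbitrary
    origin) the doubled read is searched so inserts spanning the read
    origin are still recovered, and only the first occurrence is kept.
    Returns an InsertCall with ``insert=None`` when either flank is not
    found within ``max_edit_frac`` of its length.
    """
    flank_up, flank_down = normalize(flank_up), normalize(flank_down)
    if min(len(flank_up), len(flank_down)) < MIN_FLANK_LEN:
        raise ValueError(f"flanks must be at least {MIN_FLANK_LEN} nt")
    if not 0 <= max_edit_frac < 0.5:
        raise ValueError("max_edit_frac must be in [0, 0.5)")
    read = normalize(read)
    k_up = int(max_edit_frac * len(flank_up))
    k_down = int(max_edit_frac * len(flank_down))
    for strand, seq in (("+", read), ("-", revcomp(read))):
        target = seq + seq if circular else seq
        up = _best_hit(flank_up, target, k_up)
        if up is None:
            continue
        window_start = up[1]
        window = target[window_start: window_start + len(seq)]
        down = _best_hit(flank_down, window, k_down)
        if down is None:
            continue
        insert = window[: down[0]]
        return InsertCall(read_id=read_id, strand=strand, insert=insert)
    return InsertCall(read_id=read_id)


def bin_unit_count(
    insert_length: int,
    unit_core_length: int,
    max_units: int,
    tolerance: float | None = None,
) -> int | None:
    """Nearest-multiple length binning; None when unbinnable.

    ``unit_core_length`` is the per-unit period inside the ligated insert
    (derived from the design, not the raw amplicon length).  The default
    tolerance of half a unit makes the bins tile the length axis.
    """
    if unit_core_length <= 0:
        raise ValueError("unit_core_length must be positive")
    if tolerance is None:
        tolerance = 0.5 * unit_core_length
    bin_ = round(insert_length / unit_core_length)
    if bin_ < 1 or bin_ > max_units:
        return None
    if abs(insert_length - bin_ * unit_core_length) > tolerance:
        return None
    return bin_


def assembly_efficiency(
    calls: list[InsertCall], replicates: list[str] | None = None
) -> pd.DataFrame:
    """Fraction of binned reads per unit-count bin.

    Fractions sum to 1 over binned reads; unbinned reads are excluded and
    their count reported in ``df.attrs['unbinned']``.  With per-read
    ``replicates`` labels the table holds one row per (replicate,
    unit_count) and per-bin mean fractions are in
    ``df.attrs['mean_fraction']``.
    """
    with_insert = [c for c in calls if c.insert is not None]
    if not with_insert:
        raise ValueError("no calls with an extracted insert")
    binned = [c for c in with_insert if c.unit_count is not None]
    if not binned:
        raise ValueError("no reads could be binned to a unit count")
    if replicates is None:
        counts = Counter(c.unit_count for c in binned)
        df = pd.DataFrame(
            [
                dict(unit_count=u, count=n, fraction=n / len(binned))
                for u, n in sorted(counts.items())
            ]
        )
    else:
        if len(replicates) != len(calls):
            raise ValueError("replicates must parallel calls")
        rep_of = {c.read_id: r for c, r in zip(calls, replicates)}
        rows = []
        for rep in sorted(set(replicates)):
            sub = [c for c in binned if rep_of[c.read_id] == rep]
            counts = Counter(c.unit_count for c in sub)
            rows += [
                dict(replicate=rep, unit_count=u, count=n,
                     fraction=n / len(sub))
                for u, n in sorted(counts.items())
            ]
        df = pd.DataFrame(rows)
        df.attrs["mean_fraction"] = (
            df.groupby("unit_count")["fraction"].mean().to_dict()
        )
    df.attrs["unbinned"] = len(with_insert) - len(binned)
    return df


def full_length_fraction(calls: list[InsertCall], k: int) -> float:
    """Fraction of binned reads carrying all k units."""
    df = assembly_efficiency(calls)
    row = df[df.unit_count == k]
    return float(row.fraction.iloc[0]) if len(row) else 0.0


def _target_to_query_map(cigar: str, target_len: int) -> np.ndarray:
    """query coordinate at each target coordinate (length target_len + 1)."""
    tq = np.zeros(target_len + 1, dtype=np.int64)
    q = t = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            tq[t: t + n] = q + np.arange(n)
            q += n
            t += n
        elif ch == "I":  # extra bases in query
            q += n
        elif ch == "D":  # missing from query
            tq[t: t + n] = q
            t += n
    tq[t] = q
    return tq


def _global_align(query: str, target: str) -> tuple[int, str]:
    res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], res["cigar"]


def segment_units(
    insert: str, design: ArrayDesign, unit_count: int | None = None,
    min_identity: float = 0.6,
) -> list[str]:
    """Split an insert into per-position unit subsequences.

    The insert is globally aligned to the designed insert for its unit
    count and the designed unit boundaries (multiples of the unit period)
    are projected through the alignment.  Each returned subsequence
    corresponds to one ligated unit: junction overhang + U6 + spacer +
    scaffold.
    """
    if unit_count is None:
        unit_count = bin_unit_count(
            len(insert), design.unit_core_length, design.k
        )
        if unit_count is None:
            raise SegmentationError(
                f"insert length {len(insert)} does not bin to a unit count"
            )
    expected = predicted_insert_for(design, unit_count)
    dist, cigar = _global_align(insert, expected)
    identity = 1 - dist / max(len(insert), len(expected))
    if identity < min_identity:
        raise SegmentationError(
            f"alignment identity {identity:.2f} below {min_identity:.2f}"
        )
    tq = _target_to_query_map(cigar, len(expected))
    period = design.unit_core_length
    units = []
    for i in range(unit_count):
        start = int(tq[i * period])
        end = int(tq[(i + 1) * period])
        units.append(insert[start:end])
    return units


def _alignment_columns(insert: str, expected: str) -> list[str] | None:
    """Per-expected-position aligned content of one insert.

    Column t holds the query base aligned to expected position t ("" when
    deleted); inserted bases are appended to the column on their left.
    None when the read does not align at usable identity.
    """
    dist, cigar = _global_align(insert, expected)
    if 1 - dist / max(len(insert), len(expected)) < 0.6:
        return None
    cols = [""] * len(expected)
    q = t = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for i in range(n):
                cols[t + i] = insert[q + i]
            q += n
            t += n
        elif ch == "I":
            ins = insert[q: q + n]
            if t > 0:
                cols[t - 1] += ins
            else:
                cols[0] = ins + cols[0]
            q += n
        elif ch == "D":
            t += n
    return cols


def consensus_insert(inserts: list[str], expected: str) -> str:
    """Majority-vote consensus of several reads of the same molecule.

    Each insert is aligned to the expected sequence and its bases are
    projected onto expected coordinates; per coordinate the most common
    aligned content wins (ties resolved in favour of the expected base,
    then lexicographically).  This is how per-clone long-read sequencing
    reaches consensus accuracy far above the raw read error.
    """
    if not inserts:
        raise ValueError("no inserts to build a consensus from")
    all_cols = [c for ins in inserts if (c := _alignment_columns(ins, expected))]
    if not all_cols:
        raise SegmentationError("no insert aligned to the expected sequence")
    out = []
    for t in range(len(expected)):
        votes = Counter(cols[t] for cols in all_cols)
        top = max(votes.values())
        winners = sorted(v for v, n in votes.items() if n == top)
        if expected[t] in winners:
            out.append(expected[t])
        else:
            out.append(winners[0])
    return "".join(out)


def similarity(a: str, b: str) -> float:
    """Normalized edit similarity on a 0-100 scale: 100*(1 - d/max(len))."""
    if not a and not b:
        return 100.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1 - d / max(len(a), len(b)))


def _expected_ligated(design: ArrayDesign, position: int,
                      spacer: str | None = None) -> GRNAUnit:
    """Expected ligated unit, optionally with a substituted spacer."""
    refs = design.refs
    sp = spacer if spacer is not None else design.spacers[position - 1]
    left = design.overhangs[position - 1]
    seq = left + refs.u6 + sp + refs.scaffold
    fwd_end = 4 + refs.fwd_anneal_len
    u6_end = 4 + len(refs.u6)
    sp_end = u6_end + len(sp)
    sc_end = sp_end + len(refs.scaffold)
    return GRNAUnit(
        sequence=seq,
        regions={
            "fwd_primer_region": (0, fwd_end),
            "u6": (fwd_end, u6_end),
            "spacer": (u6_end, sp_end),
            "scaffold": (sp_end, sc_end - refs.rev_anneal_len),
            "rev_primer_region": (sc_end - refs.rev_anneal_len, sc_end),
        },
    )


def extract_spacer(unit_seq: str, design: ArrayDesign, position: int = 1) -> str:
    """Observed spacer: the slice of ``unit_seq`` that the expected unit's
    spacer interval projects onto through a global alignment."""
    expected = _expected_ligated(design, position)
    _dist, cigar = _global_align(unit_seq, expected.sequence)
    tq = _target_to_query_map(cigar, len(expected.sequence))
    s, e = expected.regions["spacer"]
    return unit_seq[int(tq[s]): int(tq[e])]


def assign_grna(
    unit_seq: str,
    pool: dict[str, str],
    design: ArrayDesign,
    min_similarity: float = 80.0,
    position: int = 1,
) -> tuple[str, float]:
    """Identify a unit's gRNA against a named spacer pool.

    The observed spacer (see :func:`extract_spacer`) is scored against
    every pool member with normalized edit similarity.  Returns the best
    id when its score clears ``min_similarity`` and beats the runner-up;
    ``("ambiguous", score)`` on a tie; ``("unassigned", best)`` otherwise.
    """
    if not pool:
        raise ValueError("empty gRNA pool")
    observed = extract_spacer(unit_seq, design, position)
    scores = {gid: similarity(observed, normalize(sp))
              for gid, sp in sorted(pool.items())}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best = ranked[0]
    if best < min_similarity:
        return "unassigned", best
    if len(ranked) > 1 and ranked[1][1] == best:
        return "ambiguous", best
    return best_id, best


@dataclass
class PositionAbundanceMatrix:
    """gRNA counts per array position (plus ambiguous/unassigned columns)."""

    counts: pd.DataFrame  # index: position 1..k; columns: gRNA ids + special

    @property
    def totals(self) -> pd.Series:
        """Per-gRNA totals across all positions."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="position")


def abundance_matrix(
    full_length_calls: list[InsertCall], k: int, pool: dict[str, str]
) -> PositionAbundanceMatrix:
    """Tally per-position gRNA assignments over full-length reads."""
    columns = sorted(pool) + ["ambiguous", "unassigned"]
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, k + 1, name="position"), columns=columns
    )
    for call in full_length_calls:
        if call.unit_count != k or not call.assignments:
            continue
        for pos, (gid, _score) in enumerate(call.assignments, start=1):
            counts.loc[pos, gid] += 1
    return PositionAbundanceMatrix(counts)


def _region_of(expected: GRNAUnit, offset: int) -> str:
    for label, (s, e) in expected.regions.items():
        if s <= offset < e:
            return label
    # offset == len(sequence): attach to the rightmost region
    return list(expected.regions)[-1]


def classify_mutations(
    unit_seq: str, expected_unit: GRNAUnit, unit_position: int = 0
) -> list[MutationCall]:
    """Label every edit between an observed unit and its expected sequence.

    Substitutions are called per base; insertion/deletion runs are one
    call each.  Insertions at a region boundary attach to the region on
    their left.  Edits in the primer footprints are non-consequential.
    """
    exp = expected_unit.sequence
    if not 0.5 <= len(unit_seq) / len(exp) <= 2:
        raise ValueError(
            f"length ratio {len(unit_seq)}/{len(exp)} outside [0.5, 2]; "
            f"not a comparable unit"
        )
    _dist, cigar = _global_align(unit_seq, exp)
    calls: list[MutationCall] = []
    q = t = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            q += n
            t += n
        elif ch in "XM":
            for i in range(n):
                if unit_seq[q + i] != exp[t + i]:
                    calls.append(
                        MutationCall(
                            unit_position=unit_position,
                            region=_region_of(expected_unit, t + i),
                            kind="substitution",
                            offset=t + i,
                            ref=exp[t + i],
                            alt=unit_seq[q + i],
                        )
                    )
            q += n
            t += n
        elif ch == "I":
            calls.append(
                MutationCall(
                    unit_position=unit_position,
                    region=_region_of(expected_unit, max(t - 1, 0)),
                    kind="insertion",
                    offset=t,
                    ref="",
                    alt=unit_seq[q: q + n],
                )
            )
            q += n
        elif ch == "D":
            calls.append(
                MutationCall(
                    unit_position=unit_position,
                    region=_region_of(expected_unit, t),
                    kind="deletion",
                    offset=t,
                    ref=exp[t: t + n],
                    alt="",
                )
            )
            t += n
    return calls


def mutation_rate(unit_calls: list[list[MutationCall]]) -> float:
    """Fraction of gRNA units carrying at least one consequential mutation.

    The complement of this rate is the screening model's per-unit
    no-mutation probability p(G).
    """
    if not unit_calls:
        raise ValueError("no segmented units")
    mutated = sum(
        1 for calls in unit_calls if any(c.consequential for c in calls)
    )
    return mutated / len(unit_calls)


def clone_mutation_calls(
    read_sets: list[list[tuple[str, str]] | list[tuple[str, str, str]]],
    design: ArrayDesign,
    flank_len: int = 30,
    max_edit_frac: float = 0.2,
) -> list[list[MutationCall]]:
    """Per-unit mutation calls from per-clone sequencing runs.

    Each element of ``read_sets`` holds the reads of one individually
    sequenced clone.  Reads are extracted and binned, the modal unit count
    is taken as the clone's, a majority-vote consensus insert is built
    against the expected insert for that count, and the consensus is
    segmented and classified.  This mirrors how error rates are measured
    from individually picked clones: the consensus cancels raw long-read
    noise so the surviving edits are the clone's own.

    Returns one MutationCall list per segmented unit across all clones
    (ready for :func:`mutation_rate`); clones whose reads cannot be
    extracted or agreed on are skipped.
    """
    unit_calls: list[list[MutationCall]] = []
    for reads in read_sets:
        calls = [
            c for c in analyze_reads(
                reads, design, flank_len=flank_len,
                max_edit_frac=max_edit_frac, classify=False,
            )
            if c.insert is not None and c.unit_count is not None
        ]
        if not calls:
            continue
        counts = Counter(c.unit_count for c in calls)
        unit_count = counts.most_common(1)[0][0]
        inserts = [c.insert for c in calls if c.unit_count == unit_count]
        expected = predicted_insert_for(design, unit_count)
        try:
            consensus = consensus_insert(inserts, expected)
            units = segment_units(consensus, design, unit_count)
        except SegmentationError:
            continue
        for pos, unit_seq in enumerate(units, start=1):
            unit_calls.append(
                classify_mutations(
                    unit_seq, _expected_ligated(design, pos), unit_position=pos
                )
            )
    return unit_calls


def analyze_reads(
    reads: list[tuple[str, str]] | list[tuple[str, str, str]],
    design: ArrayDesign,
    pool: dict[str, str] | None = None,
    flank_len: int = 30,
    max_edit_frac: float = 0.2,
    min_similarity: float = 80.0,
    classify: bool = True,
    circular: bool = True,
) -> list[InsertCall]:
    """Full per-read pipeline: extract, bin, segment, assign, classify.

    Flanking sequences are taken from the design's vector backbone (its 3'
    end precedes the insert, its 5' end follows it).  When ``pool`` is
    given each unit is identified against it and mutation classification
    uses the assigned spacer; otherwise the designed spacer is expected.
    """
    backbone = design.refs.vector_backbone
    flank_up = backbone[-flank_len:]
    flank_down = backbone[:flank_len]
    results = []
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        call = extract_insert(
            seq, flank_up, flank_down, max_edit_frac=max_edit_frac,
            circular=circular, read_id=read_id,
        )
        if call.insert is None:
            results.append(call)
            continue
        call.unit_count = bin_unit_count(
            call.insert_length, design.unit_core_length, design.k
        )
        if call.unit_count is None:
            results.append(call)
            continue
        try:
            units = segment_units(call.insert, design, call.unit_count)
        except SegmentationError:
            call.segmentation_ok = False
            results.append(call)
            continue
        call.assignments = []
        call.mutations = []
        for pos, unit_seq in enumerate(units, start=1):
            assigned_spacer = None
            if pool is not None:
                gid, score = assign_grna(
                    unit_seq, pool, design, min_similarity, position=pos
                )
                call.assignments.append((gid, score))
                if gid in pool:
                    assigned_spacer = pool[gid]
            if classify:
                expected = _expected_ligated(design, pos, assigned_spacer)
                call.mutations.extend(
                    classify_mutations(unit_seq, expected, unit_position=pos)
                )
        if pool is None:
            call.assignments = None
        results.append(call)
    return results
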