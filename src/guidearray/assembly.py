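"""In-silico PCA, BsaI digestion and Golden Gate ligation.

BsaI geometry as modelled here: recognition GGTCTC, top-strand cut 1 nt
downstream of the site, bottom-strand cut 5 nt downstream, leaving 4-nt
5' overhangs.  A fragment records each sticky end as the top-strand
content of the 4-nt junction span; two ends are ligatable partners when
those top-strand 4-mers are identical (the single strands are then exact
complements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designer import ArrayDesign, PositionPrimerPair, ReferenceSet, SpacerOligo
from .dna import BSAI_SITES, min_rotation, normalize, revcomp
from .overhangs import FidelityMatrix

__all__ = [
    "Fragment",
    "VectorModel",
    "AssemblyProduct",
    "simulate_pca",
    "digest",
    "ligate_perfect",
    "ligate_stochastic",
    "enumerate_diversity",
    "make_vector",
    "design_fragments",
]

BLUNT = None
#: minimum spacing between recognition sites before cut windows collide
MIN_SITE_SPACING = 10


@dataclass(frozen=True)
class Fragment:
    """A digested dsDNA piece.

    The top-strand extent is ``left_overhang + core + right_overhang``;
    ``None`` overhangs are blunt ends.  Ligating A to B consumes A's right
    and B's left overhang (they are the two strands of the same 4-mer), so
    the joined top strand is A minus its right overhang, then B.
    """

    core: str
    left_overhang: str | None = None
    right_overhang: str | None = None
    name: str = "fragment"

    @property
    def sequence(self) -> str:
        return (self.left_overhang or "") + self.core + (self.right_overhang or "")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VectorModel:
    """Destination vector: backbone + lacZ-style dropout between two
    inward-facing BsaI sites.

    Digestion yields exactly two fragments; the backbone keeps the first
    and last junction overhangs of the design's overhang set so the array
    can close onto it.
    """

    backbone: str
    dropout: str
    left_junction: str   # backbone -> unit1 overhang
    right_junction: str  # unit_k -> backbone overhang

    @property
    def sequence(self) -> str:
        """Circular vector as a linear string with origin in the backbone."""
        cassette = (
            self.left_junction + "T" + "GAGACC"
            + self.dropout
            + "GGTCTC" + "A" + self.right_junction
        )
        return self.backbone + cassette


def make_vector(
    refs: ReferenceSet, left_junction: str, right_junction: str,
    dropout: str | None = None,
) -> VectorModel:
    """Assemble a destination vector around the reference backbone."""
    if dropout is None:
        rng = np.random.default_rng(1042)
        while True:
            dropout = "".join(rng.choice(list("ACGT"), size=300))
            # the cassette's own two sites must stay the only ones
            probe = "GAGACC" + dropout + "GGTCTC"
            if sum(probe.count(m) for m in BSAI_SITES) == 2:
                break
    return VectorModel(
        backbone=refs.vector_backbone,
        dropout=normalize(dropout),
        left_junction=normalize(left_junction),
        right_junction=normalize(right_junction),
    )


def simulate_pca(
    spacer_oligo: SpacerOligo, refs: ReferenceSet, primer_pair: PositionPrimerPair
) -> str:
    """Polymerase cycling assembly of one unit, exact-annealing model.

    The spacer oligo must match the U6 3' terminus and the scaffold 5'
    terminus exactly; the primers must anneal exactly to the outer
    reference termini.  Returns the primer-tailed amplicon.
    """
    seq = normalize(spacer_oligo.sequence)
    up = refs.u6[-refs.up_arm_len:]
    down = refs.scaffold[: refs.down_arm_len]
    if seq[: refs.up_arm_len] != up:
        off = next(
            i for i in range(refs.up_arm_len) if seq[i] != up[i]
        )
        raise ValueError(
            f"spacer oligo up arm does not anneal to U6 3' end "
            f"(first mismatch at arm offset {off})"
        )
    if seq[-refs.down_arm_len:] != down:
        tail = seq[-refs.down_arm_len:]
        off = next(
            i for i in range(refs.down_arm_len) if tail[i] != down[i]
        )
        raise ValueError(
            f"spacer oligo down arm does not anneal to scaffold 5' end "
            f"(first mismatch at arm offset {off})"
        )
    if primer_pair.fwd[-refs.fwd_anneal_len:] != refs.u6[: refs.fwd_anneal_len]:
        raise ValueError("forward primer does not anneal to the U6 5' end")
    if primer_pair.rev[-refs.rev_anneal_len:] != revcomp(
        refs.scaffold[-refs.rev_anneal_len:]
    ):
        raise ValueError("reverse primer does not anneal to the scaffold 3' end")
    spacer = seq[refs.up_arm_len: len(seq) - refs.down_arm_len]
    fwd_tail = primer_pair.fwd[: -refs.fwd_anneal_len]
    rev_tail = primer_pair.rev[: -refs.rev_anneal_len]
    return fwd_tail + refs.u6 + spacer + refs.scaffold + revcomp(rev_tail)


def _cut_spans(seq: str, topology: str) -> list[tuple[int, int]]:
    """Overhang spans [start, start+4) produced by all BsaI sites.

    Top-strand GGTCTC at i leaves the overhang at [i+7, i+11); a
    bottom-strand site (GAGACC at j on top) leaves it at [j-5, j-1).
    For circular sequences, sites and spans may wrap the origin.
    """
    n = len(seq)
    search = seq + seq[:16] if topology == "circular" else seq
    starts: set[int] = set()
    for start, motif in _find_sites_linear(search):
        if topology == "circular" and start >= n:
            continue
        s = start + 7 if motif == "GGTCTC" else start - 5
        if topology == "linear":
            if s < 0 or s + 4 > n:
                raise ValueError(
                    f"BsaI site at {start} cuts beyond the end of a "
                    f"linear sequence"
                )
        else:
            s %= n
        starts.add(s)
    return sorted((s, s + 4) for s in starts)


def _find_sites_linear(seq: str):
    hits = []
    for motif in BSAI_SITES:
        start = seq.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = seq.find(motif, start + 1)
    return sorted(hits)


def digest(seq: str, topology: str = "linear") -> list[Fragment]:
    """Cut with BsaI; returns fragments in sequence order.

    A sequence with no site comes back as one blunt fragment.  Sites whose
    cut windows are closer than MIN_SITE_SPACING raise, as the doubly-cut
    overhang would be ambiguous.
    """
    seq = normalize(seq)
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology {topology!r}")
    n = len(seq)
    spans = _cut_spans(seq, topology)
    if not spans:
        return [Fragment(core=seq)]
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 - s1 < MIN_SITE_SPACING:
            raise ValueError(
                f"cut windows at {s1} and {s2} overlap or are ambiguous "
                f"(< {MIN_SITE_SPACING} nt apart)"
            )
    frags: list[Fragment] = []
    if topology == "linear":
        first_s, first_e = spans[0]
        frags.append(Fragment(core=seq[:first_s], right_overhang=seq[first_s:first_e]))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            frags.append(
                Fragment(
                    core=seq[e1:s2],
                    left_overhang=seq[s1:e1],
                    right_overhang=seq[s2:e2],
                )
            )
        last_s, last_e = spans[-1]
        frags.append(Fragment(core=seq[last_e:], left_overhang=seq[last_s:last_e]))
    else:
        doubled = seq + seq
        closing = (spans[0][0] + n, spans[0][1] + n)
        all_spans = spans + [closing]
        if closing[0] - all_spans[-2][0] < MIN_SITE_SPACING:
            raise ValueError("circular cut windows overlap across the origin")
        for (s1, e1), (s2, e2) in zip(all_spans, all_spans[1:]):
            frags.append(
                Fragment(
                    core=doubled[e1:s2],
                    left_overhang=doubled[s1:e1],
                    right_overhang=doubled[s2:e2],
                )
            )
    return frags


@dataclass(frozen=True)
class AssemblyProduct:
    topology: str  # circular | linear
    sequence: str  # origin-normalized when circular
    part_order: tuple[str, ...]

    @property
    def unit_count(self) -> int:
        return sum(1 for p in self.part_order if p != "vector")


def _join_chain(chain: list[Fragment]) -> str:
    """Top strand of a ligated chain (each junction 4-mer counted once)."""
    parts = [(chain[0].left_overhang or "") + chain[0].core]
    for frag in chain[1:]:
        parts.append((frag.left_overhang or "") + frag.core)
    parts.append(chain[-1].right_overhang or "")
    return "".join(parts)


def ligate_perfect(
    fragments: list[Fragment], vector_backbone: Fragment
) -> AssemblyProduct:
    """Deterministic complete ligation of a uniquely-chained fragment set.

    Each junction overhang must occur exactly once as a right end and once
    as a left end across the pool; the chain starts and ends at the vector
    backbone and must close into a circle.  Fragment input order is
    irrelevant.
    """
    pool = list(fragments)
    by_left: dict[str, Fragment] = {}
    for frag in pool:
        if frag.left_overhang is None or frag.right_overhang is None:
            raise ValueError(f"fragment {frag.name!r} has a blunt end; cannot chain")
        if frag.left_overhang in by_left:
            raise ValueError(
                f"ambiguous assembly: junction overhang {frag.left_overhang!r} "
                f"is the left end of both {by_left[frag.left_overhang].name!r} "
                f"and {frag.name!r}"
            )
        by_left[frag.left_overhang] = frag
    if vector_backbone.left_overhang is None or vector_backbone.right_overhang is None:
        raise ValueError("vector backbone must carry both junction overhangs")
    chain = [vector_backbone]
    current = vector_backbone.right_overhang
    while current != vector_backbone.left_overhang:
        nxt = by_left.pop(current, None)
        if nxt is None:
            raise ValueError(
                f"broken chain: no fragment provides a left end for junction "
                f"{current!r} (position {len(chain)})"
            )
        chain.append(nxt)
        current = nxt.right_overhang
    if by_left:
        leftover = sorted(f.name for f in by_left.values())
        raise ValueError(f"fragments left out of the closed circle: {leftover}")
    seq = _join_chain(chain)
    # circularization consumes the terminal junction, present once in seq
    seq = seq[: len(seq) - 4]
    return AssemblyProduct(
        topology="circular",
        sequence=min_rotation(seq),
        part_order=tuple(f.name for f in chain),
    )


def ligate_stochastic(
    fragments: list[Fragment],
    vector_backbone: Fragment,
    m: FidelityMatrix,
    n_events: int,
    seed: int,
) -> pd.DataFrame:
    """Stochastic chain-extension ligation model.

    Each event grows a chain from the vector backbone's right end; at every
    step the free right overhang r either recruits one of the remaining
    fragments (probability proportional to ``m[r, candidate_left]``) or
    closes onto the backbone's left end (weight ``m[r, backbone_left]``).
    No re-cutting is modelled.  Products are classified by unit count;
    closure makes them circular, exhaustion leaves them linear (truncated
    chains still count at their unit count — that is what read-length
    binning observes).

    Returns a DataFrame with unit_count / topology / count / fraction.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    outcomes: dict[tuple[int, str], int] = {}
    close_oh = vector_backbone.left_overhang
    for _ in range(n_events):
        remaining = list(fragments)
        current = vector_backbone.right_overhang
        units = 0
        topology = "linear"
        while True:
            weights = [m.loc(current, f.left_overhang) for f in remaining]
            weights.append(m.loc(current, close_oh))
            total = float(sum(weights))
            if total == 0:
                break
            probs = np.asarray(weights, dtype=float) / total
            choice = int(rng.choice(len(weights), p=probs))
            if choice == len(remaining):
                topology = "circular"
                break
            frag = remaining.pop(choice)
            units += 1
            current = frag.right_overhang
        key = (units, topology)
        outcomes[key] = outcomes.get(key, 0) + 1
    rows = [
        dict(unit_count=u, topology=t, count=c, fraction=c / n_events)
        for (u, t), c in sorted(outcomes.items())
    ]
    return pd.DataFrame(rows, columns=["unit_count", "topology", "count", "fraction"])


def enumerate_diversity(pools: list[list[str]]) -> int:
    """Number of distinct ordered arrays producible from per-position pools.

    Exact integer product of pool sizes (position identity matters: the
    same guides in a different order are a different array).
    """
    for i, pool in enumerate(pools):
        if not pool:
            raise ValueError(f"position {i + 1} has an empty gRNA pool")
    return math.prod(len(pool) for pool in pools)


def design_fragments(design: ArrayDesign) -> tuple[list[Fragment], Fragment]:
    """Digest all predicted amplicons and the vector; return (unit fragments,
    backbone fragment) ready for ligation."""
    unit_frags = []
    for i, unit in enumerate(design.predicted_units):
        frags = digest(unit.sequence, "linear")
        if len(frags) != 3:
            raise ValueError(f"unit {i + 1} did not digest into 3 fragments")
        mid = frags[1]
        unit_frags.append(
            Fragment(
                core=mid.core,
                left_overhang=mid.left_overhang,
                right_overhang=mid.right_overhang,
                name=f"unit{i + 1}",
            )
        )
    vector = make_vector(
        design.refs, design.overhangs[0], design.overhangs[-1]
    )
    frags = digest(vector.sequence, "circular")
    if len(frags) != 2:
        raise ValueError("vector did not digest into backbone + dropout")
    backbone = next(
        f for f in frags if "GGTCTC" not in f.core and "GAGACC" not in f.core
    )
    backbone = Fragment(
        core=backbone.core,
        left_overhang=backbone.left_overhang,
        right_overhang=backbone.right_overhang,
        name="vector",
    )
    return unit_frags, backbone
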