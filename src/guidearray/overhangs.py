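"""Type IIS junction overhang sets and ligation-fidelity based selection.

An ordered gRNA array with k units needs k+1 distinct 4-nt junction
overhangs (vector->unit1, unit1->unit2, ..., unitk->vector).  For the
assembly to be order-faithful every overhang must anneal only to its own
complement: the set must contain no palindromes, no duplicates and no
reverse-complement pairs.  Given an empirical ligation-fidelity matrix
(e.g. exported from NEB's fidelity datasets), :func:`select_overhangs`
greedily picks a maximally orthogonal set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dna import is_dna, is_palindrome, normalize, revcomp

__all__ = [
    "OverhangSet",
    "FidelityMatrix",
    "validate_overhang_set",
    "set_fidelity",
    "select_overhangs",
    "default_fidelity_matrix",
    "default_overhang_set",
]


@dataclass(frozen=True)
class OverhangSet:
    """Ordered junction overhangs; element i is the junction left of unit i+1."""

    junction_overhangs: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(
            self,
            "junction_overhangs",
            tuple(normalize(o) for o in self.junction_overhangs),
        )

    def __len__(self) -> int:
        return len(self.junction_overhangs)

    def __iter__(self):
        return iter(self.junction_overhangs)

    def __getitem__(self, i):
        return self.junction_overhangs[i]

    @property
    def max_units(self) -> int:
        """Largest array size this set supports (junctions minus one)."""
        return len(self.junction_overhangs) - 1

    @classmethod
    def from_file(cls, path: str | Path) -> "OverhangSet":
        """Read a plain-text list (one overhang per line) or a CSV with an
        ``overhang`` column; row order is junction order."""
        path = Path(path)
        text = path.read_text()
        first = text.splitlines()[0].strip().lower() if text.strip() else ""
        if "," in first or first == "overhang":
            df = pd.read_csv(path)
            cols = {c.lower(): c for c in df.columns}
            if "overhang" not in cols:
                raise ValueError(f"{path}: CSV must have an 'overhang' column")
            items = df[cols["overhang"]].astype(str).tolist()
        else:
            items = [ln.strip() for ln in text.splitlines() if ln.strip()]
        return cls(tuple(items))

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame({"overhang": list(self.junction_overhangs)}).to_csv(
            path, index=False
        )


@dataclass
class FidelityMatrix:
    """Square matrix of relative ligation propensities.

    ``counts[i, j]`` is the propensity of overhang ``labels[i]`` ligating to
    the reverse complement of ``labels[j]``; the diagonal holds correct
    ligations.
    """

    labels: list[str]
    counts: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.labels = [normalize(l) for l in self.labels]
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} labels"
            )
        if (self.counts < 0).any():
            raise ValueError("fidelity counts must be non-negative")
        self._index = {l: i for i, l in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.counts[self._index[a], self._index[b]])
        except KeyError as e:
            raise KeyError(f"overhang {e.args[0]!r} not in fidelity matrix") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    @classmethod
    def from_csv(cls, path: str | Path) -> "FidelityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.labels, columns=self.labels).to_csv(path)


def validate_overhang_set(ohset: OverhangSet | list[str]) -> list[str]:
    """Check the four orthogonality invariants; returns violation messages.

    An empty list means the set is usable: every overhang is a 4-nt ACGT
    string, overhangs are pairwise distinct, none is self-complementary and
    no two are reverse complements of each other (either situation would
    let a junction ligate at the wrong position).
    """
    items = list(ohset)
    violations: list[str] = []
    for o in items:
        if len(o) != 4 or not is_dna(o):
            violations.append(f"{o!r} is not a 4-nt ACGT overhang")
    seen: dict[str, int] = {}
    for i, o in enumerate(items):
        if o in seen:
            violations.append(f"{o!r} appears more than once")
        seen.setdefault(o, i)
    for o in items:
        if len(o) == 4 and is_dna(o) and is_palindrome(o):
            violations.append(f"{o!r} is palindromic (self-ligation hazard)")
    for a, b in itertools.combinations(dict.fromkeys(items), 2):
        if is_dna(a) and is_dna(b) and revcomp(a) == b:
            violations.append(f"{b!r} is the reverse complement of {a!r}")
    return violations


def set_fidelity(ohset: OverhangSet | list[str], m: FidelityMatrix) -> float:
    """Expected correct-assembly fraction for a junction set under ``m``.

    For each junction i the chance of a correct ligation is modelled as
    count(i,i) / sum_j count(i,j) with j restricted to the competing set
    (the set members plus i itself); the product over junctions is
    returned.  1.0 when there is no off-diagonal mass among set members.
    """
    items = list(ohset)
    for o in items:
        if o not in m:
            raise KeyError(f"overhang {o!r} not in fidelity matrix")
    frac = 1.0
    for o in items:
        competitors = dict.fromkeys(items + [o])
        total = sum(m.loc(o, c) for c in competitors)
        correct = m.loc(o, o)
        if total == 0:
            raise ValueError(f"overhang {o!r} has zero ligation propensity")
        frac *= correct / total
    return frac


def select_overhangs(
    k: int, m: FidelityMatrix, fixed: list[str] | None = None
) -> OverhangSet:
    """Greedily pick k+1 mutually orthogonal overhangs maximizing fidelity.

    Starting from ``fixed`` (pre-pinned junctions, e.g. vector ends), each
    step adds the candidate label that maximizes the running
    :func:`set_fidelity` while keeping :func:`validate_overhang_set` clean;
    ties break lexicographically so the output is reproducible.  Greedy
    selection carries no optimality guarantee.
    """
    if k < 1:
        raise ValueError("k must be >= 1 (a 0-unit array has no junctions to design)")
    chosen = [normalize(o) for o in (fixed or [])]
    if chosen and validate_overhang_set(chosen):
        raise ValueError(
            f"fixed overhangs are not mutually valid: {validate_overhang_set(chosen)}"
        )
    for o in chosen:
        if o not in m:
            raise KeyError(f"fixed overhang {o!r} not in fidelity matrix")
    need = k + 1
    candidates = sorted(set(m.labels) - set(chosen))
    while len(chosen) < need:
        best: tuple[float, str] | None = None
        for cand in candidates:
            trial = chosen + [cand]
            if validate_overhang_set(trial):
                continue
            fid = set_fidelity(trial, m)
            # strict > keeps the lexicographically first among ties
            if best is None or fid > best[0]:
                best = (fid, cand)
        if best is None:
            raise ValueError(
                f"cannot extend to {need} mutually valid overhangs; "
                f"max achievable unit count with this matrix is {len(chosen) - 1}"
            )
        chosen.append(best[1])
        candidates.remove(best[1])
    return OverhangSet(tuple(chosen))


def default_fidelity_matrix() -> FidelityMatrix:
    """Synthetic stand-in fidelity matrix over all 256 4-mers.

    Correct ligations get weight 1000; a mismatch ligation between
    overhangs a and b decays with their Hamming distance d as 10**(3-d).
    This is not an empirical dataset — it merely ranks near-identical
    overhangs as more cross-reactive, which is the property greedy
    selection needs.  Supply a real fidelity CSV for production designs.
    """
    labels = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    arr = np.array([list(l) for l in labels])
    hamming = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    counts = 10.0 ** (3.0 - hamming)
    np.fill_diagonal(counts, 1000.0)
    return FidelityMatrix(labels, counts)


_DEFAULT_SET_CACHE: dict[int, OverhangSet] = {}


def default_overhang_set(max_units: int = 20) -> OverhangSet:
    """The bundled junction set: greedy selection from the synthetic matrix.

    Deterministic; supports arrays of up to ``max_units`` units (default 20,
    i.e. 21 junctions).
    """
    if max_units not in _DEFAULT_SET_CACHE:
        _DEFAULT_SET_CACHE[max_units] = select_overhangs(
            max_units, default_fidelity_matrix()
        )
    return _DEFAULT_SET_CACHE[max_units]
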