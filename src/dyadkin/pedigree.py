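"""Pedigree storage and kinship arithmetic.

Kinship is computed with the classical recursion (Karigl 1981)

    theta(a, a) = 1/2 (1 + F_a)
    theta(a, b) = 1/2 [theta(sire_a, b) + theta(dam_a, b)]   (a not an ancestor of b)

under the assumption that founders — individuals with both parents unknown,
including females who immigrated into the community — are unrelated and
non-inbred.  A missing parent contributes zero.  On an acyclic pedigree this
recursion agrees exactly with Wright's path-counting method.

Pairwise expected relatedness is the kinship-derived coefficient

    r(a, b) = 2 theta(a, b) / sqrt((1 + F_a)(1 + F_b))

which reduces to 2 theta for outbred pairs (parent-offspring 0.5, half sibs
0.25, first cousins 0.0625, ...).

The module also provides pedigree depth (number of complete ancestral
generations) and the detection of *cryptic* relatives: pairs unconnected on
the recorded pedigree whose genetic relatedness falls in a band (default
0.1-0.35) indicating recent, unrecorded links — typically immigrant females
sharing unsampled ancestors outside the community.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Optional

ParentPair = tuple[Optional[str], Optional[str]]


class PedigreeError(KeyError):
    """Unknown individual or malformed pedigree."""


class KinshipCalculator:
    """Incremental kinship over a growing parent map.

    Parents must be registered before their children (natural insertion
    order for a forward-in-time simulation).  Memoized results remain valid
    as individuals are appended, because adding descendants never changes
    the kinship of existing pairs.
    """

    def __init__(self) -> None:
        self.links: dict[str, ParentPair] = {}
        self._rank: dict[str, int] = {}
        self._memo: dict[tuple[str, str], float] = {}

    def add(self, ind: str, sire: Optional[str] = None, dam: Optional[str] = None) -> None:
        if ind in self.links:
            raise PedigreeError(f"duplicate individual {ind!r}")
        for p in (sire, dam):
            if p is not None and p not in self.links:
                raise PedigreeError(f"parent {p!r} of {ind!r} not yet registered")
        self.links[ind] = (sire, dam)
        self._rank[ind] = len(self._rank)

    def __contains__(self, ind: str) -> bool:
        return ind in self.links

    def parents(self, ind: str) -> ParentPair:
        try:
            return self.links[ind]
        except KeyError:
            raise PedigreeError(f"unknown individual {ind!r}") from None

    def kinship(self, a: str, b: str) -> float:
        if a not in self.links or b not in self.links:
            missing = a if a not in self.links else b
            raise PedigreeError(f"unknown individual {missing!r}")
        return self._kinship(a, b)

    def _kinship(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        if a == b:
            sire, dam = self.links[a]
            f = self._kinship(sire, dam) if sire is not None and dam is not None else 0.0
            val = 0.5 * (1.0 + f)
        else:
            # Recurse on the later-registered individual: it cannot be an
            # ancestor of the earlier one.
            if self._rank[a] < self._rank[b]:
                a, b = b, a
            sire, dam = self.links[a]
            val = 0.5 * (
                (self._kinship(sire, b) if sire is not None else 0.0)
                + (self._kinship(dam, b) if dam is not None else 0.0)
            )
        self._memo[key] = val
        return val

    def inbreeding(self, ind: str) -> float:
        """F = kinship of the individual's parents; 0 if any parent unknown."""
        sire, dam = self.parents(ind)
        if sire is None or dam is None:
            return 0.0
        return self._kinship(sire, dam)

    def relatedness(self, a: str, b: str) -> float:
        """Expected relatedness r = 2 theta / sqrt((1+F_a)(1+F_b))."""
        if a == b:
            raise PedigreeError("relatedness is defined for distinct individuals")
        theta = self.kinship(a, b)
        fa = self.inbreeding(a)
        fb = self.inbreeding(b)
        return 2.0 * theta / ((1.0 + fa) * (1.0 + fb)) ** 0.5


class Pedigree:
    """An acyclic pedigree of trio links (individual, sire, dam).

    Founders are individuals with both parents unknown and are assumed
    unrelated to each other and non-inbred.
    """

    def __init__(self, links: Mapping[str, ParentPair]):
        order = _topological_order(links)
        self._calc = KinshipCalculator()
        for ind in order:
            sire, dam = links[ind]
            self._calc.add(ind, sire, dam)
        self._order = order
        self._depth_memo: dict[str, int] = {}

    @classmethod
    def from_trios(cls, trios: Iterable[tuple[str, Optional[str], Optional[str]]]) -> "Pedigree":
        links: dict[str, ParentPair] = {}
        for ind, sire, dam in trios:
            if ind in links:
                raise PedigreeError(f"duplicate individual {ind!r}")
            links[ind] = (sire or None, dam or None)
        # parents referenced but never listed become founders
        for sire, dam in list(links.values()):
            for p in (sire, dam):
                if p is not None and p not in links:
                    links[p] = (None, None)
        return cls(links)

    @property
    def individuals(self) -> list[str]:
        """Individuals in a topological order (parents before children)."""
        return list(self._order)

    @property
    def founders(self) -> set[str]:
        return {i for i, (s, d) in self._calc.links.items() if s is None and d is None}

    def __contains__(self, ind: str) -> bool:
        return ind in self._calc

    def __len__(self) -> int:
        return len(self._calc.links)

    def parents(self, ind: str) -> ParentPair:
        return self._calc.parents(ind)

    def kinship(self, a: str, b: str) -> float:
        """Coefficient of kinship theta(a, b)."""
        return self._calc.kinship(a, b)

    def inbreeding(self, ind: str) -> float:
        return self._calc.inbreeding(ind)

    def expected_relatedness(self, a: str, b: str) -> float:
        return self._calc.relatedness(a, b)

    #: alias so a Pedigree can stand in wherever a relatedness provider is needed
    relatedness = expected_relatedness

    def depth(self, ind: str) -> int:
        """Number of complete ancestral generations.

        0 if any parent is unknown; otherwise 1 + the minimum depth of the
        parents, i.e. depth d means every ancestor through generation d is
        known while some ancestor in generation d+1 is not.
        """
        if ind not in self._calc:
            raise PedigreeError(f"unknown individual {ind!r}")
        memo = self._depth_memo
        if ind in memo:
            return memo[ind]
        # individuals are topologically ordered, so parents resolve first
        for x in self._order:
            sire, dam = self._calc.links[x]
            if sire is None or dam is None:
                memo[x] = 0
            else:
                memo[x] = 1 + min(memo[sire], memo[dam])
        return memo[ind]

    def to_trios(self) -> list[tuple[str, Optional[str], Optional[str]]]:
        return [(i, *self._calc.links[i]) for i in self._order]


def _topological_order(links: Mapping[str, ParentPair]) -> list[str]:
    """Kahn's algorithm over parent->child edges; raises on cycles."""
    children: dict[str, list[str]] = {i: [] for i in links}
    indeg: dict[str, int] = {}
    for ind, (sire, dam) in links.items():
        n = 0
        for p in (sire, dam):
            if p is not None:
                if p not in links:
                    raise PedigreeError(f"parent {p!r} of {ind!r} has no pedigree row")
                children[p].append(ind)
                n += 1
        indeg[ind] = n
    ready = sorted(i for i, n in indeg.items() if n == 0)
    order: list[str] = []
    while ready:
        x = ready.pop()
        order.append(x)
        for c in children[x]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(links):
        raise PedigreeError("pedigree contains a cycle")
    return order


def find_cryptic_pairs(
    genetic_r: Mapping[tuple[str, str], float],
    pedigree: Pedigree,
    low: float = 0.1,
    high: float = 0.35,
) -> list[tuple[str, str, float]]:
    """Pairs unconnected on the pedigree with genetic relatedness in [low, high].

    Such pairs indicate recent, unrecorded pedigree links (e.g. immigrant
    females sharing an unsampled parent).  Individuals absent from the
    pedigree are treated as founders (no recorded links).  Each unordered
    pair is considered once.
    """
    out: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()
    for (a, b), r in genetic_r.items():
        key = frozenset((a, b))
        if key in seen or a == b:
            continue
        seen.add(key)
        if a in pedigree and b in pedigree:
            expected = pedigree.expected_relatedness(a, b)
        else:
            expected = 0.0
        if expected == 0.0 and low <= r <= high:
            out.append((a, b, r))
    out.sort()
    return out


def pairs_by_expected_relatedness(
    pedigree: Pedigree,
    ids: Iterable[str],
    classes: tuple[float, ...] = (0.0, 0.0625, 0.125, 0.25, 0.5),
    per_class: int = 60,
    tol: float = 1e-9,
    rng=None,
) -> list[tuple[str, str, float]]:
    """Sample pairs whose pedigree-expected relatedness hits given values.

    Scans all unordered pairs among ``ids`` (which must be in the pedigree),
    keeps those whose expected relatedness matches one of ``classes`` within
    ``tol``, and samples up to ``per_class`` pairs per class (all of them if
    ``rng`` is None and the class has fewer).  Used to assemble validation
    panels spanning unrelated through parent-offspring pairs.
    """
    import numpy as np

    ids = list(ids)
    buckets: dict[float, list[tuple[str, str, float]]] = {c: [] for c in classes}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r = pedigree.expected_relatedness(a, b)
            for c in classes:
                if abs(r - c) <= tol:
                    buckets[c].append((a, b, r))
                    break
    out: list[tuple[str, str, float]] = []
    for c in classes:
        found = buckets[c]
        if rng is not None and len(found) > per_class:
            idx = rng.choice(len(found), size=per_class, replace=False)
            found = [found[int(k)] for k in sorted(idx)]
        out.extend(found[:per_class])
    return out


class InbreedingSummary(NamedTuple):
    n_inbred: int
    n_offspring: int
    percent: float


def documented_inbreeding(parentage, pedigree: Pedigree) -> InbreedingSummary:
    """Fraction of offspring whose recorded parents are pedigree-linked.

    Offspring with an unknown sire are excluded from the denominator (their
    parent pair cannot be checked).  A pair counts as inbreeding whenever
    the parents' kinship on the pedigree is positive.
    """
    n = linked = 0
    for rec in parentage:
        if rec.sire_id is None:
            continue
        n += 1
        if rec.mother_id in pedigree and rec.sire_id in pedigree:
            if pedigree.kinship(rec.mother_id, rec.sire_id) > 0.0:
                linked += 1
    pct = 100.0 * linked / n if n else float("nan")
    return InbreedingSummary(linked, n, pct)
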