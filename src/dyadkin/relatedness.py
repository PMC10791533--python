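"""Pairwise relatedness from genotype likelihoods via Jacquard coefficients.

For a pair of diploid individuals at a biallelic site, the four alleles fall
into one of nine condensed identity-by-descent states (Jacquard).  With
state probabilities Delta_1..Delta_9 the likelihood of observed sequencing
data at a site is

    P(data) = sum_{g1,g2} L_A(g1) L_B(g2) sum_k Delta_k P(g1, g2 | k, p)

where L are genotype likelihoods and p the population minor-allele
frequency, taken from a reference panel rather than from the (kin-dense)
focal community.  Delta is estimated by EM on this 9-component mixture —
the model behind genotype-likelihood relatedness estimators used on
low-coverage data.  From Delta we report

    theta = D1 + (D3 + D5 + D7)/2 + D8/4        (kinship)
    F_a   = D1 + D2 + D3 + D4                    (inbreeding, individual A)
    F_b   = D1 + D2 + D5 + D6
    r     = 4 theta / (2 + F_a + F_b)            (Hedrick-Lacy relatedness)

r accounts for inbreeding in either individual and reduces to 2 theta for
outbred pairs (0.5 for parent-offspring, 0.25 for half sibs, ...).

The state-conditional genotype-pair probabilities are derived by enumerating
independent allele draws per IBD class, rather than transcribing a printed
table; the enumeration is exact.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Condensed identity states: partitions of the four alleles
#: (0,1 = individual A; 2,3 = individual B) into IBD classes.
STATE_CLASSES: dict[int, tuple[tuple[int, ...], ...]] = {
    1: ((0, 1, 2, 3),),
    2: ((0, 1), (2, 3)),
    3: ((0, 1, 2), (3,)),
    4: ((0, 1), (2,), (3,)),
    5: ((0, 2, 3), (1,)),
    6: ((2, 3), (0,), (1,)),
    7: ((0, 2), (1, 3)),
    8: ((0, 2), (1,), (3,)),
    9: ((0,), (1,), (2,), (3,)),
}

N_STATES = 9


class RelatednessError(ValueError):
    """Invalid inputs or numerical failure in relatedness estimation."""


def pair_genotype_prob(g1: int, g2: int, state: int, p: float) -> float:
    """P(g1, g2 | Delta_state = 1, p) for one biallelic site.

    Each IBD class draws its allele independently (minor with probability
    ``p``); genotypes count minor-allele copies.  Exact by enumeration of
    class assignments.
    """
    if state not in STATE_CLASSES:
        raise RelatednessError(f"invalid identity state {state}")
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise RelatednessError(f"invalid genotype pair ({g1}, {g2})")
    if not 0.0 < p < 1.0:
        raise RelatednessError(f"allele frequency {p} outside (0, 1)")
    classes = STATE_CLASSES[state]
    total = 0.0
    for draw in itertools.product((0, 1), repeat=len(classes)):
        allele = {}
        w = 1.0
        for cls, x in zip(classes, draw):
            w *= p if x else 1.0 - p
            for idx in cls:
                allele[idx] = x
        if allele[0] + allele[1] == g1 and allele[2] + allele[3] == g2:
            total += w
    return total


def genotype_pair_table(p: np.ndarray) -> np.ndarray:
    """Vectorized state-conditional probability table.

    Parameters
    ----------
    p : (S,) array of minor-allele frequencies in (0, 1).

    Returns
    -------
    (9, 3, 3, S) array: ``table[k-1, g1, g2, s]`` = P(g1, g2 | state k, p_s).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise RelatednessError("allele frequencies must lie strictly in (0, 1)")
    q = 1.0 - p
    table = np.zeros((N_STATES, 3, 3, p.shape[0]))
    for k, classes in STATE_CLASSES.items():
        for draw in itertools.product((0, 1), repeat=len(classes)):
            w = np.ones_like(p)
            allele = {}
            for cls, x in zip(classes, draw):
                w = w * (p if x else q)
                for idx in cls:
                    allele[idx] = x
            g1 = allele[0] + allele[1]
            g2 = allele[2] + allele[3]
            table[k - 1, g1, g2] += w
    return table


@dataclass
class GenotypeLikelihoodMatrix:
    """Individuals x sites x 3 normalized genotype likelihoods.

    ``values[i, s]`` holds L(data | g) for g in {0, 1, 2} copies of the
    minor allele, normalized to sum to one; missing sites are all-NaN
    triples.  Sites are biallelic and autosomal.
    """

    individuals: list[str]
    sites: list[str]
    values: np.ndarray  # (n_individuals, n_sites, 3)
    alleles: Optional[np.ndarray] = None  # (n_sites, 2) allele codes

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, s = len(self.individuals), len(self.sites)
        if self.values.shape != (n, s, 3):
            raise RelatednessError(
                f"likelihood array shape {self.values.shape} != ({n}, {s}, 3)"
            )
        sums = self.values.sum(axis=2)
        ok = np.isnan(sums) | (np.abs(sums - 1.0) <= 1e-9)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise RelatednessError(
                "likelihood triple not normalized at individual "
                f"{self.individuals[bad[0]]}, site {self.sites[bad[1]]}"
            )

    @property
    def missing(self) -> np.ndarray:
        """(n_individuals, n_sites) boolean mask of missing entries."""
        return np.isnan(self.values[:, :, 0])

    def row(self, individual: str) -> np.ndarray:
        """(S, 3) likelihoods for one individual (NaN where missing)."""
        try:
            i = self.individuals.index(individual)
        except ValueError:
            raise RelatednessError(f"unknown individual {individual!r}") from None
        return self.values[i]

    def subset_sites(self, idx: np.ndarray) -> "GenotypeLikelihoodMatrix":
        idx = np.asarray(idx)
        return GenotypeLikelihoodMatrix(
            individuals=list(self.individuals),
            sites=[self.sites[i] for i in idx],
            values=self.values[:, idx, :],
            alleles=None if self.alleles is None else self.alleles[idx],
        )


def theta_from_delta(delta: np.ndarray) -> float:
    """Kinship theta = D1 + (D3 + D5 + D7)/2 + D8/4."""
    d = np.asarray(delta, dtype=float)
    return float(d[0] + 0.5 * (d[2] + d[4] + d[6]) + 0.25 * d[7])


def inbreeding_from_delta(delta: np.ndarray) -> tuple[float, float]:
    """(F_a, F_b) marginal inbreeding coefficients implied by Delta."""
    d = np.asarray(delta, dtype=float)
    return float(d[0] + d[1] + d[2] + d[3]), float(d[0] + d[1] + d[4] + d[5])


def hedrick_lacy_r(delta: np.ndarray) -> float:
    """Relatedness r = 4 theta / (2 + F_a + F_b).

    Normalizes kinship by the pair's mean self-kinship so the estimate stays
    calibrated when either individual is inbred; equals 2 theta for outbred
    pairs.
    """
    d = np.asarray(delta, dtype=float)
    if d.shape != (9,):
        raise RelatednessError("Delta must have nine components")
    if np.any(d < -1e-8) or abs(d.sum() - 1.0) > 1e-8:
        raise RelatednessError("Delta is not a valid probability simplex")
    fa, fb = inbreeding_from_delta(d)
    return 4.0 * theta_from_delta(d) / (2.0 + fa + fb)


@dataclass
class RelatednessEstimate:
    """Maximum-likelihood Jacquard coefficients for one pair."""

    pair: tuple[str, str]
    delta: np.ndarray  # (9,)
    n_sites: int
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    @property
    def theta(self) -> float:
        return theta_from_delta(self.delta)

    @property
    def f_a(self) -> float:
        return inbreeding_from_delta(self.delta)[0]

    @property
    def f_b(self) -> float:
        return inbreeding_from_delta(self.delta)[1]

    @property
    def r(self) -> float:
        return hedrick_lacy_r(self.delta)


def _shared_state_likelihoods(
    gl_a: np.ndarray,
    gl_b: np.ndarray,
    freqs: np.ndarray,
    table: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-site likelihood of each identity state, on shared sites.

    Returns (S_shared, 9) array ``PK[s, k-1] = sum_{g1,g2} L_A(g1) L_B(g2)
    P(g1, g2 | k, p_s)``.
    """
    gl_a = np.asarray(gl_a, dtype=float)
    gl_b = np.asarray(gl_b, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if gl_a.shape != gl_b.shape or gl_a.ndim != 2 or gl_a.shape[1] != 3:
        raise RelatednessError("genotype-likelihood arrays must both be (S, 3)")
    if freqs.shape[0] != gl_a.shape[0]:
        raise RelatednessError("frequency vector length mismatch")
    shared = ~(np.isnan(gl_a[:, 0]) | np.isnan(gl_b[:, 0]))
    if not shared.any():
        raise RelatednessError("no shared non-missing sites for this pair")
    a = gl_a[shared]
    b = gl_b[shared]
    t = table[:, :, :, shared] if table is not None else genotype_pair_table(freqs[shared])
    # PK[s, k] = sum_{g1,g2} a[s,g1] b[s,g2] t[k,g1,g2,s]
    pk = np.einsum("sg,sh,kghs->sk", a, b, t, optimize=True)
    return pk


def pair_loglik(
    gl_a: np.ndarray,
    gl_b: np.ndarray,
    freqs: np.ndarray,
    delta: np.ndarray,
    table: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of Delta for one pair, summed over shared sites."""
    pk = _shared_state_likelihoods(gl_a, gl_b, freqs, table)
    site = pk @ np.asarray(delta, dtype=float)
    if np.any(site <= 0.0) or not np.all(np.isfinite(site)):
        bad = int(np.argmin(site))
        raise RelatednessError(f"non-finite site likelihood at shared site index {bad}")
    return float(np.log(site).sum())


def em_estimate(
    gl_a: np.ndarray,
    gl_b: np.ndarray,
    freqs: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 2,
    seed: Optional[int] = None,
    table: Optional[np.ndarray] = None,
    pair: tuple[str, str] = ("A", "B"),
) -> RelatednessEstimate:
    """EM estimate of the nine Jacquard coefficients for one pair.

    The per-site state likelihoods form a 9-component mixture; the E-step
    computes per-site posteriors over states and the M-step averages them.
    Starts from the simplex barycentre plus ``n_restarts`` seeded Dirichlet
    restarts, keeping the best optimum.  The log-likelihood is monotone
    non-decreasing across iterations; iteration stops when it improves by
    less than ``tol`` or after ``max_iter`` iterations.
    """
    pk = _shared_state_likelihoods(gl_a, gl_b, freqs, table)
    n_shared = pk.shape[0]
    if n_shared < 100:
        warnings.warn(
            f"only {n_shared} shared sites for pair {pair}; estimates may be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    starts = [np.full(N_STATES, 1.0 / N_STATES)]
    starts += [rng.dirichlet(np.ones(N_STATES)) for _ in range(n_restarts)]

    best = None
    pk_t = np.ascontiguousarray(pk.T)
    for start in starts:
        delta = start.copy()
        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            site = pk @ delta
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = float(np.log(site).sum())
            if not np.isfinite(ll):
                bad = int(np.argmin(site))
                raise RelatednessError(
                    f"non-finite likelihood for pair {pair} at shared site index {bad}"
                )
            trace.append(ll)
            # E-step posterior column sums without materializing the (S, 9)
            # responsibility matrix: mean_s delta_k pk[s,k] / site_s
            delta = delta * (pk_t @ (1.0 / site)) / n_shared
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        final_ll = pair_loglik(gl_a, gl_b, freqs, delta, table)
        if best is None or final_ll > best.loglik:
            best = RelatednessEstimate(
                pair=pair,
                delta=delta,
                n_sites=n_shared,
                loglik=final_ll,
                n_iter=len(trace),
                converged=converged,
                loglik_trace=np.asarray(trace),
            )
    return best


def relatedness_table(
    gl: GenotypeLikelihoodMatrix,
    freqs: np.ndarray,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    seed: Optional[int] = None,
    **em_kwargs,
):
    """Relatedness estimates for many pairs, sharing one probability table.

    Parameters
    ----------
    gl : genotype likelihoods for all individuals involved.
    freqs : (S,) reference-panel minor-allele frequencies.
    pairs : pairs to estimate; all unordered pairs if None.
    seed : base seed; each pair gets an independent substream.

    Returns
    -------
    pandas.DataFrame with columns a, b, n_sites, d1..d9, theta, f_a, f_b,
    r, loglik — the relatedness lookup consumed by the pair-table builder.
    """
    import pandas as pd

    freqs = np.asarray(freqs, dtype=float)
    table = genotype_pair_table(freqs)
    if pairs is None:
        ids = gl.individuals
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    ss = np.random.SeedSequence(seed)
    rows = []
    for (a, b), child in zip(pairs, ss.spawn(len(pairs))):
        est = em_estimate(
            gl.row(a),
            gl.row(b),
            freqs,
            table=table,
            seed=child.generate_state(1)[0] % (2**31),
            pair=(a, b),
            **em_kwargs,
        )
        row = dict(a=a, b=b, n_sites=est.n_sites)
        for k in range(9):
            row[f"d{k+1}"] = est.delta[k]
        row.update(theta=est.theta, f_a=est.f_a, f_b=est.f_b, r=est.r, loglik=est.loglik)
        rows.append(row)
    return pd.DataFrame(rows)


def lookup_from_table(df) -> dict[tuple[str, str], float]:
    """Symmetric (a, b) -> r mapping from a relatedness table."""
    out: dict[tuple[str, str], float] = {}
    for a, b, r in zip(df["a"], df["b"], df["r"]):
        out[(a, b)] = float(r)
        out[(b, a)] = float(r)
    return out


def hard_call(gl: GenotypeLikelihoodMatrix) -> np.ndarray:
    """(n, S) maximum-likelihood genotypes; -1 where missing."""
    vals = np.where(np.isnan(gl.values), -np.inf, gl.values)
    calls = np.argmax(vals, axis=2).astype(np.int8)
    calls[gl.missing] = -1
    return calls


class HWETest(NamedTuple):
    lrt: float
    p_value: float


def hwe_test(n0: int, n1: int, n2: int) -> HWETest:
    """1-df likelihood-ratio test of Hardy-Weinberg proportions.

    Compares free genotype frequencies against HWE at the maximum-likelihood
    allele frequency, on genotype counts (n0, n1, n2).
    """
    n = n0 + n1 + n2
    if n == 0:
        return HWETest(0.0, 1.0)
    counts = np.array([n0, n1, n2], dtype=float)
    p = (2 * n2 + n1) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return HWETest(0.0, 1.0)
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        free = np.where(counts > 0, counts / n, 1.0)
        ll_free = float((counts * np.log(free)).sum())
        ll_hwe = float((counts * np.log(hwe)).sum())
    lrt = max(0.0, 2.0 * (ll_free - ll_hwe))
    return HWETest(lrt, float(stats.chi2.sf(lrt, df=1)))


def site_filters(
    gl: GenotypeLikelihoodMatrix,
    min_ind_frac: float = 0.9,
    hwe_alpha: float = 0.001,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Indices of sites retained for relatedness estimation.

    Applied to the reference-panel individuals: a site is kept when the
    fraction of panel individuals with data is at least ``min_ind_frac``,
    the Hardy-Weinberg LRT p-value (on hard-called genotype counts) is at
    least ``hwe_alpha``, and the hard-call minor-allele frequency is at
    least ``maf_min``.
    """
    calls = hard_call(gl)
    n_ind = calls.shape[0]
    keep = []
    for s in range(calls.shape[1]):
        c = calls[:, s]
        obs = c[c >= 0]
        if obs.size < min_ind_frac * n_ind:
            continue
        n0 = int((obs == 0).sum())
        n1 = int((obs == 1).sum())
        n2 = int((obs == 2).sum())
        maf = (2 * n2 + n1) / (2 * obs.size)
        maf = min(maf, 1.0 - maf)
        if maf < maf_min:
            continue
        if hwe_test(n0, n1, n2).p_value < hwe_alpha:
            continue
        keep.append(s)
    return np.asarray(keep, dtype=int)


class ValidationResult(NamedTuple):
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n_pairs: int


def validate_against_pedigree(
    estimates: Sequence[RelatednessEstimate],
    pedigree,
) -> ValidationResult:
    """OLS of genetic relatedness on pedigree-expected relatedness.

    Regresses the genotype-likelihood estimates of r on the path-counting
    expectation for every pair whose members are both in the pedigree;
    high R-squared validates the genetic estimator.  Requires >= 3 pairs.
    """
    xs, ys = [], []
    for est in estimates:
        a, b = est.pair
        if a in pedigree and b in pedigree:
            xs.append(pedigree.expected_relatedness(a, b))
            ys.append(est.r)
    if len(xs) < 3:
        raise RelatednessError(
            f"pedigree validation needs >= 3 pairs with pedigree links, got {len(xs)}"
        )
    fit = stats.linregress(xs, ys)
    return ValidationResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_pairs=len(xs),
    )
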