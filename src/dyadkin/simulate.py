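"""Synthetic community, pedigree and genotype-likelihood generator.

Emulates the demographic and genetic structure the analysis pipeline
assumes: a multi-generation primate community with overlapping generations,
female-biased but incomplete dispersal (females emigrate at the dispersal
age with a configurable probability, 0.5 by default), ongoing immigration
of young females, unlinked biallelic SNPs with reference-panel allele
frequencies, and sequencing-noise genotype likelihoods (Poisson depth,
per-base error).

Mate choice carries an inbreeding-avoidance knob: a sire is drawn among
co-resident reproductively aged males with probability proportional to
exp(-gamma * r(mother, male)), where r is the expected relatedness on the
*hidden* pedigree (which, unlike the observable one, includes the external
ancestry of immigrant females).  gamma = 0 is uniform random mating, so the
simulator provides both the null and the alternative for the downstream
avoidance model.

Immigrant females carry hidden two-generation external pedigrees; external
families occasionally share parents or grandparents, planting cryptic
relative pairs (half sibs, cousins) that the recorded pedigree calls
unrelated.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .demography import (
    GESTATION_DAYS,
    IndividualRecord,
    ParentageRecord,
    add_years,
    conception_date,
)
from .pedigree import KinshipCalculator, Pedigree
from .relatedness import GenotypeLikelihoodMatrix

logger = logging.getLogger(__name__)

Date = dt.date


class ExtinctionError(RuntimeError):
    """The simulated community died out; raise birth/immigration rates."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic community.

    Demographic defaults mirror the target system: ~50% of natal females
    emigrate at the 13-year dispersal age, immigrants arrive at 13, and
    generations overlap over a multi-decade horizon.  Genetic defaults give
    unlinked biallelic SNPs with minor-allele frequencies uniform on
    (0.05, 0.5) and low-coverage likelihoods (mean depth 8x, base error 1%).
    """

    n_founders: int = 40
    years: int = 45
    start_year: int = 1970
    birth_prob: float = 0.22  # per resident adult female per year
    female_emigration_prob: float = 0.5
    annual_immigration: float = 1.2  # Poisson mean of arriving females/year
    dispersal_age: int = 13
    female_fertility_age: float = 13.0
    male_min_sire_age: float = 10.5
    infant_mortality: float = 0.04  # annual hazard, age < 5
    adult_mortality: float = 0.02  # annual hazard, 5 <= age < 35
    senescent_mortality: float = 0.15  # annual hazard, age >= 35
    founder_age_min: float = 8.0
    founder_age_max: float = 35.0
    avoidance_gamma: float = 0.0
    # hidden external pedigree structure of immigrants
    immigrant_family_reuse_prob: float = 0.2  # same parents -> full sibs
    immigrant_parent_share_prob: float = 0.2  # one shared parent -> half sibs
    external_grandpair_share_prob: float = 0.4  # shared grandparents -> cousins
    genotyped_min_age: float = 2.0
    # genetics
    n_sites: int = 10_000
    maf_min: float = 0.05
    maf_max: float = 0.5
    mean_depth: float = 8.0
    base_error: float = 0.01
    panel_size: int = 60
    panel_depth: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "birth_prob",
            "female_emigration_prob",
            "infant_mortality",
            "adult_mortality",
            "senescent_mortality",
            "immigrant_family_reuse_prob",
            "immigrant_parent_share_prob",
            "external_grandpair_share_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.avoidance_gamma < 0:
            raise ValueError("avoidance_gamma must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth hidden from the observable files."""

    hidden_pedigree: Pedigree
    natality: dict[str, str]
    sires: dict[str, str]
    gamma: float
    external_ids: set[str]
    genotypes: Optional[dict[str, np.ndarray]] = None


@dataclass
class SyntheticCommunity:
    records: list[IndividualRecord]
    parentage: list[ParentageRecord]
    pedigree: Pedigree  # observable: immigrants and founders unlinked
    truth: SyntheticTruth
    config: SimulationConfig


class _Ind:
    __slots__ = (
        "id",
        "sex",
        "birth",
        "entry",
        "arrival",
        "death",
        "emigration",
        "natality",
        "resident",
    )

    def __init__(self, id, sex, birth, natality, entry, arrival=None):
        self.id = id
        self.sex = sex
        self.birth = birth
        self.entry = entry  # first day of community residency
        self.arrival = arrival
        self.death = None
        self.emigration = None
        self.natality = natality
        self.resident = True

    def age(self, when: Date) -> float:
        return (when - self.birth).days / 365.25

    def resident_on(self, when: Date) -> bool:
        if when < self.entry:
            return False
        for end in (self.death, self.emigration):
            if end is not None and when > end:
                return False
        return True


def mate_choice(
    mother: str,
    candidate_males: list[str],
    gamma: float,
    hidden_pedigree,
    rng: np.random.Generator,
) -> Optional[str]:
    """Draw a sire with probability proportional to exp(-gamma * r).

    ``hidden_pedigree`` may be a :class:`Pedigree`, a
    :class:`KinshipCalculator`, or any object with a
    ``relatedness(a, b) -> float`` method.  gamma = 0 is uniform random
    mating.  Returns None when no candidate is available (no conception
    that cycle).
    """
    if not candidate_males:
        return None
    rel = np.array(
        [hidden_pedigree.relatedness(mother, m) for m in candidate_males], dtype=float
    )
    w = np.exp(-gamma * rel)
    w /= w.sum()
    return candidate_males[int(rng.choice(len(candidate_males), p=w))]


class _ExternalWorld:
    """Hidden ancestry of immigrant females.

    External individuals form families (parent pairs) whose members are
    themselves children of external grandpairs; families sometimes reuse
    parents or grandpairs, so some immigrants are full sibs, half sibs or
    first cousins without any recorded link.
    """

    def __init__(self, config: SimulationConfig, kin: KinshipCalculator):
        self.cfg = config
        self.kin = kin
        self.families: list[tuple[str, str]] = []
        self.grandpairs: list[tuple[str, str]] = []
        self.counter = 0
        self.ids: set[str] = set()

    def _new_id(self) -> str:
        self.counter += 1
        ident = f"X{self.counter:04d}"
        self.ids.add(ident)
        return ident

    def _new_grandpair(self) -> tuple[str, str]:
        gp = (self._new_id(), self._new_id())
        for g in gp:
            self.kin.add(g)
        self.grandpairs.append(gp)
        return gp

    def _new_parent(self, rng) -> str:
        if self.grandpairs and rng.random() < self.cfg.external_grandpair_share_prob:
            gp = self.grandpairs[int(rng.integers(len(self.grandpairs)))]
        else:
            gp = self._new_grandpair()
        parent = self._new_id()
        self.kin.add(parent, gp[0], gp[1])
        return parent

    def family_for_immigrant(self, rng) -> tuple[str, str]:
        if self.families and rng.random() < self.cfg.immigrant_family_reuse_prob:
            return self.families[int(rng.integers(len(self.families)))]
        if self.families and rng.random() < self.cfg.immigrant_parent_share_prob:
            shared_sire, _ = self.families[int(rng.integers(len(self.families)))]
            fam = (shared_sire, self._new_parent(rng))
        else:
            fam = (self._new_parent(rng), self._new_parent(rng))
        self.families.append(fam)
        return fam


def simulate_community(
    config: SimulationConfig, seed: Optional[int] = None
) -> SyntheticCommunity:
    """Run the annual event loop and emit observable records plus truth.

    Yearly order: deaths, immigrant arrivals, female emigration at the
    dispersal age, then births via :func:`mate_choice`.  The observable
    pedigree masks immigrant ancestry (immigrants become founders) and the
    founding generation's natality is recorded as unknown.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    start = dt.date(cfg.start_year, 1, 1)
    kin = KinshipCalculator()
    world = _ExternalWorld(cfg, kin)
    inds: dict[str, _Ind] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"N{counter:04d}"

    def rand_day(year: int) -> Date:
        return dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))

    for _ in range(cfg.n_founders):
        ident = new_id()
        sex = "female" if rng.random() < 0.5 else "male"
        age = rng.uniform(cfg.founder_age_min, cfg.founder_age_max)
        birth = start - dt.timedelta(days=int(age * 365.25))
        inds[ident] = _Ind(ident, sex, birth, "unknown", entry=start)
        kin.add(ident)

    def mortality(age: float) -> float:
        if age < 5:
            return cfg.infant_mortality
        if age < 35:
            return cfg.adult_mortality
        return cfg.senescent_mortality

    parentage: list[ParentageRecord] = []
    sires: dict[str, str] = {}

    for yr in range(cfg.years):
        year = cfg.start_year + yr
        jan1 = dt.date(year, 1, 1)
        # deaths
        for ind in list(inds.values()):
            if ind.death is None and (ind.emigration is None):
                if rng.random() < mortality(ind.age(jan1)):
                    ind.death = rand_day(year)
                    ind.resident = False
        # immigrant arrivals
        for _ in range(rng.poisson(cfg.annual_immigration)):
            ident = new_id()
            arrival = rand_day(year)
            birth = add_years(arrival, -cfg.dispersal_age)
            imm = _Ind(ident, "female", birth, "immigrant", entry=arrival, arrival=arrival)
            inds[ident] = imm
            sire, dam = world.family_for_immigrant(rng)
            kin.add(ident, sire, dam)
        # natal female emigration at dispersal age
        for ind in inds.values():
            if (
                ind.sex == "female"
                and ind.natality == "natal"
                and ind.death is None
                and ind.emigration is None
            ):
                birthday = add_years(ind.birth, cfg.dispersal_age)
                if birthday.year == year and rng.random() < cfg.female_emigration_prob:
                    ind.emigration = birthday + dt.timedelta(days=int(rng.integers(0, 120)))
                    ind.resident = False
        # births
        mothers = [
            i
            for i in inds.values()
            if i.sex == "female"
            and i.death is None
            and i.emigration is None
            and i.age(jan1) >= cfg.female_fertility_age
        ]
        for mother in mothers:
            if rng.random() >= cfg.birth_prob:
                continue
            birth = rand_day(year)
            conc = conception_date(birth)
            if conc < mother.entry:
                continue  # conceived before joining: cannot be a community birth
            candidates = sorted(
                i.id
                for i in inds.values()
                if i.sex == "male"
                and i.resident_on(conc)
                and i.age(conc) >= cfg.male_min_sire_age
            )
            sire = mate_choice(mother.id, candidates, cfg.avoidance_gamma, kin, rng)
            if sire is None:
                continue
            child_id = new_id()
            sex = "female" if rng.random() < 0.5 else "male"
            inds[child_id] = _Ind(child_id, sex, birth, "natal", entry=birth)
            kin.add(child_id, sire, mother.id)
            parentage.append(ParentageRecord(child_id, mother.id, sire, birth))
            sires[child_id] = sire
        resident = [i for i in inds.values() if i.death is None and i.emigration is None]
        if not any(i.sex == "male" for i in resident) or not any(
            i.sex == "female" for i in resident
        ):
            raise ExtinctionError(
                f"community extinct in year {year}; increase birth_prob, "
                "annual_immigration or n_founders"
            )

    end = dt.date(cfg.start_year + cfg.years, 1, 1)
    records: list[IndividualRecord] = []
    natality_truth: dict[str, str] = {}
    for ind in inds.values():
        res_start = ind.entry
        res_end = ind.death or ind.emigration
        final_age_date = ind.death or end
        genotyped = ind.age(final_age_date) >= cfg.genotyped_min_age
        records.append(
            IndividualRecord(
                id=ind.id,
                sex=ind.sex,
                birth_date=ind.birth,
                birth_date_known=ind.natality == "natal",
                death_date=ind.death,
                natality=ind.natality,
                immigration_date=ind.arrival,
                emigration_date=ind.emigration,
                residency=[(res_start, res_end)],
                in_genetic_dataset=genotyped,
            )
        )
        natality_truth[ind.id] = ind.natality

    observed = Pedigree.from_trios(
        [(i, sires.get(i), kin.links[i][1] if i in sires else None) for i in inds]
    )
    hidden = Pedigree(dict(kin.links))
    truth = SyntheticTruth(
        hidden_pedigree=hidden,
        natality=natality_truth,
        sires=sires,
        gamma=cfg.avoidance_gamma,
        external_ids=set(world.ids),
    )
    return SyntheticCommunity(
        records=records,
        parentage=parentage,
        pedigree=observed,
        truth=truth,
        config=cfg,
    )


def draw_site_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-site minor-allele frequencies, uniform on [maf_min, maf_max]."""
    return rng.uniform(config.maf_min, config.maf_max, config.n_sites)


def gene_drop(
    pedigree: Pedigree, freqs: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Mendelian gene dropping of unlinked biallelic sites down a pedigree.

    Founders draw genotypes Binomial(2, p) per site; each non-founder
    inherits one uniformly chosen allele from each parent, independently
    across sites.  Returns minor-allele dosage arrays per individual.
    """
    freqs = np.asarray(freqs, dtype=float)
    genotypes: dict[str, np.ndarray] = {}
    for ind in pedigree.individuals:
        sire, dam = pedigree.parents(ind)
        if sire is None and dam is None:
            g = rng.binomial(2, freqs).astype(np.int8)
        else:
            alleles = np.zeros(freqs.shape[0], dtype=np.int8)
            for parent in (sire, dam):
                if parent is None:
                    alleles += rng.binomial(1, freqs).astype(np.int8)
                else:
                    pg = genotypes[parent]
                    alleles += rng.binomial(1, pg / 2.0).astype(np.int8)
            g = alleles
        genotypes[ind] = g
    return genotypes


def sample_unrelated(n: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, S) genotypes of unrelated individuals at HWE."""
    return rng.binomial(2, np.asarray(freqs, dtype=float), size=(n, len(freqs))).astype(
        np.int8
    )


def allele_frequencies(genotypes: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Sample allele frequencies from a genotype matrix (n, S).

    A small pseudocount keeps estimates strictly inside (0, 1) even when a
    site is monomorphic in the finite panel; such sites are normally removed
    by the MAF filter anyway.
    """
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    return (g.sum(axis=0) + pseudocount) / (2.0 * n + 2.0 * pseudocount)


def simulate_gls(
    genotypes: np.ndarray,
    mean_depth: float,
    base_error: float,
    rng: np.random.Generator,
    individuals: Optional[list[str]] = None,
    sites: Optional[list[str]] = None,
) -> GenotypeLikelihoodMatrix:
    """Sequencing-noise genotype likelihoods from true genotypes.

    Per individual-site: depth ~ Poisson(mean_depth) (depth 0 => missing);
    the minor-allele read count is Binomial(depth, q_g) with q_g in
    {error, 1/2, 1 - error} for dosage g in {0, 1, 2}; the three genotype
    likelihoods are the binomial pmfs, normalized to sum to one.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= base_error < 0.5:
        raise ValueError("base_error must lie in [0, 0.5)")
    g = np.atleast_2d(np.asarray(genotypes))
    n, s = g.shape
    depth = rng.poisson(mean_depth, size=(n, s))
    q_true = np.array([base_error, 0.5, 1.0 - base_error])[g]
    k = rng.binomial(depth, q_true)
    values = np.empty((n, s, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        for gg, q in enumerate((base_error, 0.5, 1.0 - base_error)):
            # binomial coefficient cancels in the normalization
            if q == 0.0:
                lik = np.where(k == 0, 1.0, 0.0)
            elif q == 1.0:
                lik = np.where(k == depth, 1.0, 0.0)
            else:
                lik = np.exp(k * np.log(q) + (depth - k) * np.log1p(-q))
            values[:, :, gg] = lik
    total = values.sum(axis=2, keepdims=True)
    values = np.divide(values, total, out=np.full_like(values, np.nan), where=total > 0)
    values[depth == 0] = np.nan
    return GenotypeLikelihoodMatrix(
        individuals=individuals or [f"I{k}" for k in range(n)],
        sites=sites or [f"site{k}" for k in range(s)],
        values=values,
    )


@dataclass
class SimulatedDataset:
    """A full synthetic study: community, genotypes, likelihoods, panel."""

    community: SyntheticCommunity
    freqs_true: np.ndarray
    freqs_panel: np.ndarray
    gl: GenotypeLikelihoodMatrix  # genotyped community members
    panel_gl: GenotypeLikelihoodMatrix
    site_ids: list[str]


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """Community simulation plus genetics: the full observable study.

    Gene-drops the *hidden* pedigree (so cryptic immigrant kinship is in
    the genotypes), simulates low-coverage likelihoods for genotyped
    community members, and simulates an unrelated reference panel from the
    same site frequencies; panel sample frequencies stand in for the
    "high-quality subset" allele-frequency estimates.
    """
    master = np.random.default_rng(config.seed if seed is None else seed)
    s_comm, s_freq, s_drop, s_gl, s_panel = master.spawn(5)
    community = simulate_community(config, seed=s_comm)
    freqs = draw_site_frequencies(config, s_freq)
    genotypes = gene_drop(community.truth.hidden_pedigree, freqs, s_drop)
    community.truth.genotypes = genotypes

    genotyped = [r.id for r in community.records if r.in_genetic_dataset]
    site_ids = [f"site{k}" for k in range(config.n_sites)]
    gmat = np.stack([genotypes[i] for i in genotyped])
    gl = simulate_gls(
        gmat, config.mean_depth, config.base_error, s_gl, individuals=genotyped, sites=site_ids
    )
    panel_geno = sample_unrelated(config.panel_size, freqs, s_panel)
    panel_gl = simulate_gls(
        panel_geno,
        config.panel_depth,
        config.base_error,
        s_panel,
        individuals=[f"P{k}" for k in range(config.panel_size)],
        sites=site_ids,
    )
    freqs_panel = allele_frequencies(panel_geno)
    return SimulatedDataset(
        community=community,
        freqs_true=freqs,
        freqs_panel=freqs_panel,
        gl=gl,
        panel_gl=panel_gl,
        site_ids=site_ids,
    )
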