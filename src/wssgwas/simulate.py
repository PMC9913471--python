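"""Synthetic boar-station datasets with planted truth.

Generates a multi-generation pedigree under random mating, gene-dropped
SNP genotypes (founders at Hardy–Weinberg with Beta-distributed allele
frequencies, Poisson crossovers at 1 cM/Mb), a handful of large-effect
QTL plus a polygenic remainder, and repeated semen-type records per boar
following the repeatability model

    y = fixed(year–season, parity) + age·b1 + interval·b2 + a + pe + e.

Defaults mirror the study conditions the pipeline targets: 583
phenotyped boars with 5–103 records each (mean ≈ 44) collected over
2020–2022, an 18-autosome ≈ 2.26 Gb genome carrying 38,054 post-QC
SNPs, additive/permanent/residual variances (30, 35, 111) on a
motility-like percentage scale, and 5 QTL jointly explaining ≈ 22 % of
the additive variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .data import season_of as _season
from .pedigree import Pedigree

#: approximate Sus scrofa 11.1 autosome lengths (Mb), chromosomes 1–18
PIG_AUTOSOME_MB = (
    274, 151, 133, 131, 105, 171, 121, 139, 139,
    69, 79, 61, 208, 141, 140, 80, 63, 56,
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the target study regime."""

    # pedigree
    n_founders: int = 120
    n_generations: int = 4  # bred generations after the founders
    generation_size: int = 450
    n_sires: int = 40
    n_dams: int = 200
    n_boars: int = 583  # phenotyped & genotyped males, last generation
    # genome / markers
    n_snps: int = 38_054
    chromosome_lengths_bp: tuple[int, ...] = tuple(
        int(mb * 1_000_000) for mb in PIG_AUTOSOME_MB
    )
    founder_freq_beta: tuple[float, float] = (2.0, 2.0)
    min_founder_maf: float = 0.05
    recombination_cm_per_mb: float = 1.0
    # genetic architecture
    n_qtl: int = 5
    qtl_variance_fractions: tuple[float, ...] = (0.06, 0.05, 0.04, 0.04, 0.03)
    polygenic: str = "genomic"  # or "pedigree" (infinitesimal, no markers)
    # variance scale (motility-like trait, % units)
    sigma_a2: float = 30.0
    sigma_p2: float = 35.0
    sigma_e2: float = 111.0
    # records
    trait: str = "spmot"
    trait_mean: float = 82.0
    records_min: int = 5
    records_mean: float = 44.0
    records_max: int = 103
    mean_interval_days: float = 7.0
    year_season_sd: float = 3.0
    parity_sd: float = 1.5
    age_slope: float = 0.08  # trait units per month of age
    interval_slope: float = 0.05  # trait units per day of interval
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.qtl_variance_fractions[: self.n_qtl]) >= 1.0:
            raise ValueError("QTL variance fractions must sum to < 1")
        if min(self.sigma_a2, self.sigma_p2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class TruthTable:
    """Planted simulation truth for checking every downstream stage."""

    breeding_values: pd.DataFrame  # animal_id, tbv
    qtl: pd.DataFrame  # snp_index, snp_id, chrom, pos, effect, variance_fraction
    realized_h2: float
    realized_repeatability: float


@dataclass
class SimulatedData:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator):
    """Discrete-generation random-mating pedigree.

    Returns (Pedigree, sex array, generation array). The last bred
    generation holds exactly ``n_boars`` males — the phenotyped cohort.
    """
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[int] = []  # 1 male, 2 female
    gen: list[int] = []

    for i in range(cfg.n_founders):
        ids.append(f"F{i:04d}")
        sire.append(-1)
        dam.append(-1)
        sex.append(1 if i < cfg.n_founders // 2 else 2)
        gen.append(0)

    for g in range(1, cfg.n_generations + 1):
        last = g == cfg.n_generations
        size = cfg.n_boars if last else cfg.generation_size
        prev = [i for i in range(len(ids)) if gen[i] == g - 1]
        males = [i for i in prev if sex[i] == 1]
        females = [i for i in prev if sex[i] == 2]
        sires = rng.choice(males, size=min(cfg.n_sires, len(males)), replace=False)
        dams = rng.choice(females, size=min(cfg.n_dams, len(females)), replace=False)
        # each dam is mated to one sire; offspring sample a dam, giving
        # full- and half-sib family structure
        mate_of = {d: rng.choice(sires) for d in dams}
        for k in range(size):
            d = dams[rng.integers(len(dams))]
            ids.append(f"G{g}_{k:04d}")
            sire.append(int(mate_of[d]))
            dam.append(int(d))
            sex.append(1 if last else (1 if rng.random() < 0.5 else 2))
            gen.append(g)

    triples = [
        (
            ids[i],
            ids[sire[i]] if sire[i] >= 0 else "0",
            ids[dam[i]] if dam[i] >= 0 else "0",
        )
        for i in range(len(ids))
    ]
    ped = Pedigree.from_triples(triples)
    order = [ped.position(a) for a in ids]
    sex_arr = np.empty(len(ids), dtype=np.int8)
    gen_arr = np.empty(len(ids), dtype=np.int32)
    sex_arr[order] = sex
    gen_arr[order] = gen
    return ped, sex_arr, gen_arr


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNP positions ~ uniform per chromosome, count ∝ chromosome length."""
    lengths = np.asarray(cfg.chromosome_lengths_bp, dtype=float)
    counts = np.floor(cfg.n_snps * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the largest chromosomes
    for c in np.argsort(-lengths)[: cfg.n_snps - counts.sum()]:
        counts[c] += 1
    rows = []
    for c, (n_c, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.choice(int(length) - 1, size=n_c, replace=False)) + 1
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    snp_map = pd.concat(rows, ignore_index=True)
    snp_map.insert(0, "snp_id", [f"snp{c}_{p}" for c, p in
                                 zip(snp_map["chrom"], snp_map["pos"])])
    return snp_map


def simulate_genotypes(
    cfg: SimulationConfig, ped: Pedigree, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gene-drop haplotypes through the pedigree.

    Founder haplotypes are Bernoulli(p) draws (Hardy–Weinberg) at
    Beta-sampled frequencies truncated to ``min_founder_maf``; gametes
    recombine with Poisson crossover counts at 1 cM/Mb, no interference.
    Returns (haplotypes of every pedigree animal, SNP map); genotype
    codes are the haplotype sums.
    """
    snp_map = _snp_map(cfg, rng)
    n_snps = len(snp_map)
    a, b = cfg.founder_freq_beta
    freq = rng.beta(a, b, size=n_snps)
    freq = np.clip(freq, cfg.min_founder_maf, 1.0 - cfg.min_founder_maf)

    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    chrom_slices = {
        c: slice(int(np.flatnonzero(chrom == c)[0]), int(np.flatnonzero(chrom == c)[-1] + 1))
        for c in np.unique(chrom)
    }
    morgans = {
        c: cfg.chromosome_lengths_bp[c - 1] / 1e6 * cfg.recombination_cm_per_mb / 100.0
        for c in chrom_slices
    }

    n = len(ped)
    hap = np.empty((n, 2, n_snps), dtype=np.int8)

    def gamete(parent: int) -> np.ndarray:
        g = np.empty(n_snps, dtype=np.int8)
        for c, sl in chrom_slices.items():
            k = rng.poisson(morgans[c])
            start = rng.integers(2)
            if k == 0:
                g[sl] = hap[parent, start, sl]
                continue
            xo = np.sort(rng.integers(1, cfg.chromosome_lengths_bp[c - 1], size=k))
            chooser = (start + np.searchsorted(xo, pos[sl])) % 2
            g[sl] = np.where(chooser == 0, hap[parent, 0, sl], hap[parent, 1, sl])
        return g

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for which, par in ((0, s), (1, d)):
            if par < 0:
                hap[i, which] = (rng.random(n_snps) < freq).astype(np.int8)
            else:
                hap[i, which] = gamete(par)
    return hap, snp_map


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _breeding_values(
    cfg: SimulationConfig,
    ped: Pedigree,
    codes_all: np.ndarray | None,
    snp_map: pd.DataFrame | None,
    boar_rows: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """True breeding values: QTL contributions + polygenic remainder.

    Each component is rescaled so its variance across the phenotyped
    boars matches its target share of σa².
    """
    n = len(ped)
    fractions = np.asarray(cfg.qtl_variance_fractions[: cfg.n_qtl], dtype=float)
    qtl_rows = []
    tbv = np.zeros(n)

    if cfg.n_qtl > 0:
        if codes_all is None:
            raise ValueError("QTL architecture requires simulated genotypes")
        maf = np.minimum(codes_all[boar_rows].mean(axis=0) / 2.0,
                         1 - codes_all[boar_rows].mean(axis=0) / 2.0)
        eligible = np.flatnonzero(maf >= 0.1)
        # spread QTL over distinct chromosomes where possible
        chosen: list[int] = []
        chroms_used: set = set()
        for j in rng.permutation(eligible):
            c = snp_map["chrom"].iat[int(j)]
            if c not in chroms_used:
                chosen.append(int(j))
                chroms_used.add(c)
            if len(chosen) == cfg.n_qtl:
                break
        for j in rng.permutation(eligible):  # fill up if chromosomes ran out
            if len(chosen) == cfg.n_qtl:
                break
            if int(j) not in chosen:
                chosen.append(int(j))
        for j, frac in zip(chosen, fractions):
            z = codes_all[:, j].astype(float)
            z = z - z[boar_rows].mean()
            sd = z[boar_rows].std()
            effect = np.sqrt(frac * cfg.sigma_a2) / sd
            tbv += effect * z
            qtl_rows.append(
                {
                    "snp_index": j,
                    "snp_id": snp_map["snp_id"].iat[j],
                    "chrom": snp_map["chrom"].iat[j],
                    "pos": snp_map["pos"].iat[j],
                    "effect": effect,
                    "variance_fraction": frac,
                }
            )

    rem_var = (1.0 - fractions.sum()) * cfg.sigma_a2
    if rem_var > 0:
        if cfg.polygenic == "pedigree" or codes_all is None:
            # infinitesimal flow through the pedigree: founders N(0, σ²),
            # offspring = parent average + Mendelian sampling
            d = ped.mendelian_sampling_variance()
            u = np.zeros(n)
            for i in range(n):
                s, dd = ped.sire[i], ped.dam[i]
                mid = 0.0
                if s >= 0:
                    mid += 0.5 * u[s]
                if dd >= 0:
                    mid += 0.5 * u[dd]
                u[i] = mid + rng.normal(0.0, np.sqrt(d[i]))
            scale = np.sqrt(rem_var) / max(u[boar_rows].std(), 1e-12)
            tbv += u * scale
        else:
            qtl_set = {int(r["snp_index"]) for r in qtl_rows}
            bg = np.array([j for j in range(codes_all.shape[1]) if j not in qtl_set])
            beta = rng.normal(size=bg.size)
            zc = codes_all[:, bg].astype(float)
            zc -= zc[boar_rows].mean(axis=0)
            u = zc @ beta
            scale = np.sqrt(rem_var) / max(u[boar_rows].std(), 1e-12)
            tbv += u * scale

    qtl = pd.DataFrame(
        qtl_rows,
        columns=["snp_index", "snp_id", "chrom", "pos", "effect", "variance_fraction"],
    )
    return tbv, qtl


def simulate_phenotypes(
    cfg: SimulationConfig,
    ped: Pedigree,
    tbv: np.ndarray,
    boar_rows: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, float, float]:
    """Repeated records for the phenotyped boars per the repeatability model."""
    # per-boar record counts: shifted negative binomial matching the
    # target min/mean/max (mean ≈ 44, sd ≈ 26 at defaults)
    mean_extra = cfg.records_mean - cfg.records_min
    if mean_extra <= 0:
        counts = np.full(len(boar_rows), cfg.records_min)
    else:
        var_extra = max((0.6 * cfg.records_mean) ** 2, mean_extra * 1.5)
        r = mean_extra**2 / (var_extra - mean_extra)
        p_nb = r / (r + mean_extra)
        counts = cfg.records_min + rng.negative_binomial(r, p_nb, size=len(boar_rows))
        counts = np.clip(counts, cfg.records_min, cfg.records_max)

    ys_levels = [f"{y}_{s}" for y in (2020, 2021, 2022)
                 for s in ("spring", "summer", "autumn", "winter")]
    ys_eff = dict(zip(ys_levels, rng.normal(0, cfg.year_season_sd, len(ys_levels))))
    parity_eff = dict(zip(range(1, 7), rng.normal(0, cfg.parity_sd, 6)))

    pe = rng.normal(0, np.sqrt(cfg.sigma_p2), size=len(boar_rows))

    start = pd.Timestamp("2020-01-01")
    horizon = pd.Timestamp("2022-12-31")
    rows = []
    for b, (row_i, n_rec) in enumerate(zip(boar_rows, counts)):
        boar = ped.ids[row_i]
        parity = int(rng.integers(1, 7))
        age0 = float(rng.uniform(8, 14))  # months at first collection
        gaps = 1 + rng.poisson(cfg.mean_interval_days - 1, size=n_rec)
        first = start + pd.Timedelta(days=int(rng.integers(0, 365)))
        day = 0
        for k in range(n_rec):
            if k > 0:
                day += int(gaps[k])
            date = first + pd.Timedelta(days=day)
            if date > horizon:
                break
            age = age0 + day / 30.44
            interval = int(gaps[k])
            resid = rng.normal(0, np.sqrt(cfg.sigma_e2))
            ys = f"{date.year}_{_season(date.month)}"
            value = (
                cfg.trait_mean
                + ys_eff[ys]
                + parity_eff[parity]
                + cfg.age_slope * age
                + cfg.interval_slope * interval
                + tbv[row_i]
                + pe[b]
                + resid
            )
            rows.append(
                {
                    "boar_id": boar,
                    "collection_date": date,
                    "year_season": ys,
                    "parity": parity,
                    "age_months": round(age, 2),
                    "interval_days": interval,
                    "volume_ml": round(float(np.clip(rng.normal(250, 60), 20, None)), 1),
                    cfg.trait: round(float(value), 3),
                }
            )
    pheno = pd.DataFrame(rows)
    total = cfg.sigma_a2 + cfg.sigma_p2 + cfg.sigma_e2
    var_a = float(np.var(tbv[boar_rows]))
    realized_h2 = var_a / total if total > 0 else 0.0
    realized_re = (var_a + float(np.var(pe))) / total if total > 0 else 0.0
    return pheno, realized_h2, realized_re




# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedData:
    """Generate a complete dataset (pedigree, genotypes, phenotypes, truth)."""
    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    ped, sex, gen = simulate_pedigree(cfg, rng)
    boar_rows = np.flatnonzero((gen == cfg.n_generations) & (sex == 1))

    geno = None
    codes_all = None
    snp_map = None
    if cfg.n_snps > 0:
        hap, snp_map = simulate_genotypes(cfg, ped, rng)
        codes_all = hap.sum(axis=1, dtype=np.int8)
        geno = GenotypeMatrix(
            [ped.ids[i] for i in boar_rows], codes_all[boar_rows].copy(), snp_map
        )

    tbv, qtl = _breeding_values(cfg, ped, codes_all, snp_map, boar_rows, rng)
    pheno, h2, re = simulate_phenotypes(cfg, ped, tbv, boar_rows, rng)
    truth = TruthTable(
        breeding_values=pd.DataFrame({"animal_id": ped.ids, "tbv": tbv}),
        qtl=qtl,
        realized_h2=h2,
        realized_repeatability=re,
    )
    return SimulatedData(cfg, ped, geno, pheno, truth)


#: named deterministic fixtures: a small one for oracle-style checks and
#: the full study-scale configuration
FIXTURES: dict[str, SimulationConfig] = {
    "tiny": SimulationConfig(
        n_founders=12,
        n_generations=2,
        generation_size=14,
        n_sires=4,
        n_dams=6,
        n_boars=12,
        n_snps=200,
        chromosome_lengths_bp=(40_000_000, 30_000_000),
        n_qtl=2,
        qtl_variance_fractions=(0.2, 0.15),
        records_mean=8.0,
        records_max=15,
    ),
    "paper-like": SimulationConfig(),
}


def make_fixture(name: str, seed: int = 0, **overrides) -> SimulatedData:
    """Named deterministic dataset; keyword overrides adjust the config."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    cfg = replace(FIXTURES[name], seed=seed, **overrides)
    return simulate(cfg)
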