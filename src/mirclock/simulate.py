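"""Pedigreed synthetic cohorts with miRNA/mRNA expression, covariates,
survival, and cardiometabolic traits.

The generator emulates a two-cohort family study profiled for whole-blood
miRNA expression on the qPCR cycle-threshold (Ct) scale: founders are drawn
from an older cohort (mean age 66, SD 9) and their children from a younger
one (mean 46, SD 9); miRNA Ct values carry linear age effects (mostly
positive on the Ct scale, i.e. expression declining with age), a polygenic
term correlated through the pedigree, technical-covariate effects sized so
that normalization removes a realistic share of variance, and detection
censoring at Ct 27.  mRNA expression mixes a blood-cell signature, latent
batch factors and negative (expression-scale) coupling to designated
"target" miRNAs.  Mortality follows an exponential proportional-hazards
model driven by a latent aging deviation (delta-age) with administrative
censoring; traits are linear/logistic functions of age and the same latent
deviation.

Every generating parameter (per-miRNA age slope and heritability, coupling
map, planted seed-match sites, hazard coefficients, latent delta-age) is
returned as ground truth so downstream stages can be tested by parameter
recovery.  Identical :class:`SimParams` (including the seed) give identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirclock.exceptions import AlignmentError, ConfigurationError
from mirclock import io as mio

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

# Trait generator coefficients: (intercept at age 55, per-year-of-age slope,
# per-year-of-latent-delta-age slope, residual SD).
DEFAULT_TRAIT_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "sbp": (122.0, 0.55, 0.10, 14.0),
    "dbp": (73.0, 0.08, 0.06, 9.0),
    "glucose": (101.0, 0.31, 0.07, 18.0),
    "total_cholesterol": (186.0, 0.82, -0.05, 33.0),
    "hdl": (59.0, 0.07, 0.06, 18.0),
    "triglycerides": (115.0, 0.26, -0.18, 70.0),
    "bmi": (28.0, 0.004, -0.002, 5.5),
}

# Binary outcomes: (logit intercept at age 55, per-year log-odds for age,
# per-year log-odds for latent delta-age).
DEFAULT_BINARY_EFFECTS: dict[str, tuple[float, float, float]] = {
    "chd": (-3.6, 0.09, 0.06),
    "hypertension": (-0.6, 0.08, 0.03),
    "diabetes": (-2.6, 0.06, 0.02),
}


@dataclass
class SimParams:
    """Generator configuration; defaults are the desk-scale study conditions."""

    n_families: int = 300
    family_size_min: int = 3
    family_size_max: int = 6
    founder_age_mean: float = 66.0
    founder_age_sd: float = 9.0
    child_age_mean: float = 46.0
    child_age_sd: float = 9.0
    min_age: float = 24.0
    confound_batch_with_cohort: bool = True
    n_batches: int = 50
    # miRNA panel
    n_mirna: int = 150
    frac_age_affected: float = 127.0 / 150.0
    frac_ct_positive: float = 103.0 / 127.0  # of affected: beta>0 on Ct scale
    beta_age_range: tuple[float, float] = (0.03, 0.11)  # |Ct units per year|
    mirna_h2: float = 0.30
    genetic_env_var: float = 1.0  # sigma_A^2 + sigma_E^2 per miRNA, Ct^2
    biological_state_sd: float = 12.0  # shared non-age variance on the age axis, years
    mirna_baseline_range: tuple[float, float] = (16.0, 23.5)
    sex_effect_sd: float = 0.15
    tech_var_frac_range: tuple[float, float] = (0.25, 0.55)
    detection_limit: float = 27.0
    # mRNA / cells
    n_mrna: int = 300
    n_cell_types: int = 5
    cell_dirichlet: tuple[float, ...] = (12.0, 5.0, 2.0, 1.0, 0.5)
    cell_signal_sd: float = 1.0
    n_batch_factors: int = 3
    batch_factor_sd: float = 0.7
    n_coupled_pairs: int = 30
    coupling_strength: float = 0.6  # log2 units per SD of miRNA expression
    mrna_noise_sd: float = 1.0
    # latent aging deviation and outcomes
    delta_age_sd: float = 5.0
    delta_age_h2: float = 0.38
    baseline_hazard: float = 0.012  # events per person-year at age 55
    age_log_hr: float = 0.085
    sex_log_hr: float = 0.3
    log_hr_per_year: float = 0.0953  # per year of latent delta-age (HR 1.10)
    follow_up_years: float = 6.0
    trait_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS))
    binary_effects: dict = field(default_factory=lambda: dict(DEFAULT_BINARY_EFFECTS))
    # sequences
    mirna_length: int = 22
    utr3_length: int = 500
    utr5_length: int = 200
    cds_length: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_age_affected", "frac_ct_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("mirna_h2", "delta_age_h2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1)")
        for name in ("n_families", "n_mirna", "n_mrna"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.family_size_min < 3 or self.family_size_max < self.family_size_min:
            raise ConfigurationError("family sizes must satisfy 3 <= min <= max")
        if not 10.0 <= self.detection_limit <= 40.0:
            raise ConfigurationError("detection limit outside plausible Ct range 10-40")
        if len(self.cell_dirichlet) != self.n_cell_types:
            raise ConfigurationError("cell_dirichlet length must equal n_cell_types")


def simulate_pedigrees(params: SimParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Nuclear families (two founders plus children) drawn from the
    configured size distribution; deterministic given the seed."""
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    rows = []
    for f in range(params.n_families):
        fam = f"F{f:04d}"
        size = int(rng.integers(params.family_size_min, params.family_size_max + 1))
        father = f"{fam}_1"
        mother = f"{fam}_2"
        rows.append((fam, father, mio.FOUNDER, mio.FOUNDER, "male"))
        rows.append((fam, mother, mio.FOUNDER, mio.FOUNDER, "female"))
        for c in range(size - 2):
            sex = "male" if rng.random() < 0.5 else "female"
            rows.append((fam, f"{fam}_{c + 3}", father, mother, sex))
    ped = pd.DataFrame(rows, columns=mio.PEDIGREE_COLUMNS)
    mio.validate_pedigree(ped)
    return ped


_BLOCK_CACHE: dict[tuple, list] = {}


def _family_blocks(ped: pd.DataFrame) -> list[tuple[list[str], np.ndarray]]:
    """Per-pedigree relationship blocks (2*kinship), in pedigree order.

    Cached on the pedigree's row content: repeated phenotype draws over one
    pedigree (e.g. replicate experiments) skip the kinship recursion.
    """
    from mirclock.lmm import kinship_from_pedigree

    key = tuple(map(tuple, ped[["individual_id", "father_id", "mother_id"]].values))
    if key in _BLOCK_CACHE:
        return _BLOCK_CACHE[key]
    blocks = []
    for fam, sub in ped.groupby("pedigree_id", sort=False):
        K = kinship_from_pedigree(sub)
        blocks.append((list(K.index), K.values))
    if len(_BLOCK_CACHE) > 8:  # keep the cache tiny
        _BLOCK_CACHE.clear()
    _BLOCK_CACHE[key] = blocks
    return blocks


def _polygenic_draws(
    ped: pd.DataFrame, n_traits: int, var_a: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n_traits additive-genetic vectors with covariance var_a * K,
    exploiting the block-diagonal family structure."""
    parts = []
    for ids, K in _family_blocks(ped):
        w, U = np.linalg.eigh(K)
        L = U * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((len(ids), n_traits))
        parts.append(pd.DataFrame(np.sqrt(var_a) * (L @ z), index=ids))
    return pd.concat(parts)


def simulate_phenotypes(
    ped: pd.DataFrame, params: SimParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype/covariate table plus per-sample ground truth.

    Founders take the older-cohort age distribution, children the younger;
    technical covariates are independent of age; traits and survival are
    driven by age and a kinship-correlated latent delta-age.  Returns
    ``(phenotypes, truth)`` where truth holds the latent delta-age and
    cohort label per sample.
    """
    rng = np.random.default_rng(params.rng_seed + 1) if rng is None else rng
    ids = ped["individual_id"].tolist()
    n = len(ids)
    is_founder = ((ped["father_id"] == mio.FOUNDER) & (ped["mother_id"] == mio.FOUNDER)).values

    age = np.where(
        is_founder,
        rng.normal(params.founder_age_mean, params.founder_age_sd, n),
        rng.normal(params.child_age_mean, params.child_age_sd, n),
    )
    age = np.clip(age, params.min_age, None)
    sex = ped["sex"].values

    if params.confound_batch_with_cohort:
        half = params.n_batches // 2
        batch = np.where(
            is_founder,
            rng.integers(0, half, n),
            rng.integers(half, params.n_batches, n),
        )
    else:
        batch = rng.integers(0, params.n_batches, n)

    # latent aging deviation: polygenic + environmental
    var_a = params.delta_age_h2 * params.delta_age_sd**2
    var_e = (1.0 - params.delta_age_h2) * params.delta_age_sd**2
    g = _polygenic_draws(ped, 1, var_a, rng).loc[ids, 0].values
    delta = g + rng.normal(0.0, np.sqrt(var_e), n)

    phen = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    phen["age"] = age
    phen["sex"] = sex
    phen["batch"] = [f"B{b:02d}" for b in batch]
    phen["rna_concentration"] = rng.normal(100.0, 15.0, n)
    phen["rin"] = rng.normal(8.0, 0.5, n)
    phen["ratio_260_280"] = rng.normal(2.0, 0.08, n)

    age_c = age - 55.0
    for trait, (icpt, b_age, b_delta, sd) in params.trait_effects.items():
        phen[trait] = icpt + b_age * age_c + b_delta * delta + rng.normal(0.0, sd, n)
    phen["smoker"] = (rng.random(n) < 0.09).astype(int)
    for trait, (icpt, b_age, b_delta) in params.binary_effects.items():
        logit = icpt + b_age * age_c + b_delta * delta
        phen[trait] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    # treatment flags: most prevalent cases treated, plus an age-driven base rate
    phen["rx_htn"] = ((phen["hypertension"] == 1) & (rng.random(n) < 0.75)).astype(int)
    phen["rx_dm"] = ((phen["diabetes"] == 1) & (rng.random(n) < 0.6)).astype(int)
    p_lipid = 1.0 / (1.0 + np.exp(-(-1.5 + 0.05 * age_c)))
    phen["rx_lipid"] = (rng.random(n) < p_lipid).astype(int)

    # exponential proportional hazards with administrative censoring
    log_h = (
        np.log(params.baseline_hazard)
        + params.age_log_hr * age_c
        + params.sex_log_hr * (sex == "male")
        + params.log_hr_per_year * delta
    )
    t = rng.exponential(1.0, n) / np.exp(log_h)
    event = (t <= params.follow_up_years).astype(int)
    phen["surv_time"] = np.minimum(t, params.follow_up_years)
    phen["surv_event"] = event

    truth = pd.DataFrame(
        {
            "latent_delta_age": delta,
            "polygenic_delta_age": g,
            "cohort": np.where(is_founder, "older", "younger"),
        },
        index=phen.index,
    )
    return phen, truth


def simulate_mirna_ct(
    ped: pd.DataFrame,
    phen: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
    latent_delta: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct matrix (NaN = not expressed, above the detection limit) plus
    per-miRNA generating truth.

    Age-affected miRNAs load on a shared biological-age axis B = (age - 55)
    + latent delta-age + shared state noise, so Ct = baseline + beta_age*B
    + sex effect + technical effects + polygenic term (covariance
    sigma_A^2 * relationship) + residual noise.  The marginal slope of Ct
    on age is exactly beta_age (the other components of B are independent
    of age), but the shared axis caps how well any multivariate predictor
    can recover chronological age -- mirroring the modest clock
    correlations whole-blood panels achieve.  A configurable majority of
    age-affected miRNAs get beta_age > 0 on the Ct scale, i.e. expression
    declining with age.
    """
    rng = np.random.default_rng(params.rng_seed + 2) if rng is None else rng
    ids = ped["individual_id"].tolist()
    if not set(ids) <= set(phen.index):
        missing = sorted(set(ids) - set(phen.index))[:5]
        raise AlignmentError(f"phenotypes missing pedigree members, e.g. {missing}")
    phen = phen.loc[ids]
    n, m = len(ids), params.n_mirna
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(m)]

    n_affected = int(round(params.frac_age_affected * m))
    n_pos = int(round(params.frac_ct_positive * n_affected))
    beta = np.zeros(m)
    mag = rng.uniform(*params.beta_age_range, n_affected)
    sign = np.array([1.0] * n_pos + [-1.0] * (n_affected - n_pos))
    affected_idx = rng.choice(m, n_affected, replace=False)
    beta[affected_idx] = mag * rng.permutation(sign)

    baseline = rng.uniform(*params.mirna_baseline_range, m)
    sex_eff = rng.normal(0.0, params.sex_effect_sd, m)
    age_c = phen["age"].values - 55.0
    delta = (
        latent_delta.loc[ids].values if latent_delta is not None else np.zeros(n)
    )
    state = rng.normal(0.0, params.biological_state_sd, n)
    bio_age = age_c + delta + state  # shared axis the affected panel reads out
    male = (phen["sex"].values == "male").astype(float)

    # technical structure: per-batch random shifts plus linear covariate terms,
    # scaled per miRNA so technical variance is the configured share of the
    # age+sex+genetic+residual variance
    batches = phen["batch"].values
    uniq_b = pd.unique(batches)
    b_index = pd.Series(np.arange(len(uniq_b)), index=uniq_b)[batches].values
    batch_shifts = rng.standard_normal((len(uniq_b), m))
    zc = _zscore(phen["rna_concentration"].values)
    zr = _zscore(phen["rin"].values)
    zq = _zscore(phen["ratio_260_280"].values)
    coef = rng.standard_normal((3, m))
    tech_raw = batch_shifts[b_index, :] + zc[:, None] * coef[0] + zr[:, None] * coef[1] + zq[:, None] * coef[2]
    tech_raw = tech_raw - tech_raw.mean(axis=0)
    raw_var = tech_raw.var(axis=0)
    raw_var[raw_var == 0] = 1.0

    base_var = (beta**2) * bio_age.var() + sex_eff**2 * 0.25 + params.genetic_env_var
    frac = rng.uniform(*params.tech_var_frac_range, m)
    tech_var = frac / (1.0 - frac) * base_var
    tech = tech_raw * np.sqrt(tech_var / raw_var)

    var_a = params.mirna_h2 * params.genetic_env_var
    var_e = (1.0 - params.mirna_h2) * params.genetic_env_var
    g = _polygenic_draws(ped, m, var_a, rng).loc[ids].values
    eps = rng.normal(0.0, np.sqrt(var_e), (n, m))

    ct = (
        baseline[None, :]
        + beta[None, :] * bio_age[:, None]
        + sex_eff[None, :] * male[:, None]
        + tech
        + g
        + eps
    )
    censored = ct >= params.detection_limit
    ct = pd.DataFrame(np.where(censored, np.nan, ct), index=phen.index, columns=mirna_ids)

    truth = pd.DataFrame(
        {
            "beta_age": beta,
            "age_affected": beta != 0.0,
            "h2": np.where(params.genetic_env_var > 0, params.mirna_h2, 0.0),
            "baseline": baseline,
            "sex_effect": sex_eff,
            "tech_var_frac": frac,
            "censored_frac": censored.mean(axis=0),
        },
        index=pd.Index(mirna_ids, name="mirna_id"),
    )
    return ct, truth


def simulate_mrna_and_cells(
    ct: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
    coupling: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """mRNA log2 matrix, true cell proportions, and the miRNA->mRNA
    coupling map.

    mRNA = gene mean + cell-mixture signal + latent batch factors + coupled
    miRNA terms (negative on the expression scale for target pairs) + noise.
    Cell proportions are Dirichlet and sum to one per sample.
    """
    rng = np.random.default_rng(params.rng_seed + 3) if rng is None else rng
    samples = ct.index
    n = len(samples)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(params.n_mrna)]

    if coupling is None:
        coupling = default_coupling(ct.columns.tolist(), gene_ids, params, rng)
    unknown = set(coupling["mirna_id"]) - set(ct.columns)
    if unknown:
        raise ConfigurationError(f"coupling references unknown miRNAs: {sorted(unknown)[:5]}")

    cells = rng.dirichlet(params.cell_dirichlet, n)
    cell_names = [f"cell{c + 1}" for c in range(params.n_cell_types)]
    W = rng.standard_normal((params.n_cell_types, params.n_mrna)) * params.cell_signal_sd
    # scale so the mixture carries signal comparable to the noise
    mrna = 8.0 + 6.0 * (cells - cells.mean(axis=0)) @ W

    if params.n_batch_factors > 0:
        F = rng.standard_normal((n, params.n_batch_factors))
        G = rng.standard_normal((params.n_batch_factors, params.n_mrna)) * params.batch_factor_sd
        mrna = mrna + F @ G

    # miRNA expression on the expression scale = -z(Ct); coupling negative
    # on that scale, hence positive against Ct
    filled = ct.fillna(params.detection_limit)
    gcol = {g: j for j, g in enumerate(gene_ids)}
    for mir, gene, strength in coupling[["mirna_id", "mrna_id", "strength"]].itertuples(index=False):
        expr_z = -_zscore(filled[mir].values)
        mrna[:, gcol[gene]] += -strength * expr_z

    mrna = mrna + rng.normal(0.0, params.mrna_noise_sd, (n, params.n_mrna))
    mrna_df = pd.DataFrame(mrna, index=samples, columns=gene_ids)
    cells_df = pd.DataFrame(cells, index=samples, columns=cell_names)
    return mrna_df, cells_df, coupling


def default_coupling(
    mirna_ids: list[str], gene_ids: list[str], params: SimParams, rng: np.random.Generator
) -> pd.DataFrame:
    """One coupled target gene per pair for the first n_coupled_pairs genes,
    each tied to a random miRNA, at the default strength."""
    k = min(params.n_coupled_pairs, len(gene_ids))
    mirs = rng.choice(mirna_ids, k, replace=True)
    return pd.DataFrame(
        {"mirna_id": mirs, "mrna_id": gene_ids[:k], "strength": params.coupling_strength}
    )


def simulate_sequences(
    params: SimParams,
    coupling: pd.DataFrame,
    mirna_ids: list[str],
    gene_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Random-background mature miRNA (RNA) and transcript-region (DNA)
    sequences with one 8mer seed-match site planted in the 3'UTR of every
    coupled target pair.  Returns (mirna_fasta, region_fasta, planted_sites)
    with 0-based half-open planted coordinates."""
    rng = np.random.default_rng(params.rng_seed + 4) if rng is None else rng
    mirna_seqs = {
        m: "".join(rng.choice(list("ACGU"), params.mirna_length)) for m in mirna_ids
    }
    regions: dict[str, str] = {}
    lengths = {"5UTR": params.utr5_length, "CDS": params.cds_length, "3UTR": params.utr3_length}
    for g in gene_ids:
        for region, L in lengths.items():
            regions[f"{g}|{region}"] = "".join(rng.choice(list("ACGT"), L))

    planted = []
    for mir, gene in coupling[["mirna_id", "mrna_id"]].itertuples(index=False):
        seed7 = mirna_seqs[mir][1:8]
        site = _revcomp_dna(seed7) + "A"  # 8mer: seed match plus A opposite position 1
        key = f"{gene}|3UTR"
        seq = regions[key]
        pos = int(rng.integers(1, len(seq) - len(site) - 1))
        regions[key] = seq[:pos] + site + seq[pos + len(site):]
        planted.append((mir, gene, "3UTR", pos, pos + len(site)))
    planted_df = pd.DataFrame(
        planted, columns=["mirna_id", "mrna_id", "region", "start", "end"]
    )
    return mirna_seqs, regions, planted_df


@dataclass
class SyntheticCohort:
    """Bundle of all generator outputs plus ground truth."""

    params: SimParams
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame
    phenotype_truth: pd.DataFrame
    ct: pd.DataFrame
    mirna_truth: pd.DataFrame
    mrna: pd.DataFrame
    cells: pd.DataFrame
    coupling: pd.DataFrame
    mirna_seqs: dict[str, str]
    region_seqs: dict[str, str]
    planted_sites: pd.DataFrame

    def to_dir(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_pedigree(self.pedigree, out / "pedigree.tsv")
        mio.write_phenotypes(self.phenotypes, out / "phenotypes.tsv")
        mio.write_matrix_tsv(self.ct, out / "mirna_ct.tsv")
        mio.write_matrix_tsv(self.mrna, out / "mrna_log2.tsv")
        mio.write_matrix_tsv(self.cells, out / "cell_proportions.tsv")
        self.mirna_truth.to_csv(out / "truth_mirna.tsv", sep="\t")
        self.phenotype_truth.to_csv(out / "truth_samples.tsv", sep="\t")
        self.coupling.to_csv(out / "truth_coupling.tsv", sep="\t", index=False)
        self.planted_sites.to_csv(out / "truth_planted_sites.tsv", sep="\t", index=False)
        mio.write_fasta(sorted(self.mirna_seqs.items()), out / "mirna_mature.fasta")
        mio.write_fasta(sorted(self.region_seqs.items()), out / "transcript_regions.fasta")
        with open(out / "params.txt", "w") as fh:
            for f_ in dataclasses.fields(self.params):
                fh.write(f"{f_.name}\t{getattr(self.params, f_.name)}\n")


def simulate_cohort(params: SimParams | None = None) -> SyntheticCohort:
    """Run the full generator with a single seed controlling every stage."""
    params = SimParams() if params is None else params
    ped = simulate_pedigrees(params)
    phen, phen_truth = simulate_phenotypes(ped, params)
    ct, mirna_truth = simulate_mirna_ct(
        ped, phen, params, latent_delta=phen_truth["latent_delta_age"]
    )
    mrna, cells, coupling = simulate_mrna_and_cells(ct, params)
    mirna_seqs, region_seqs, planted = simulate_sequences(
        params, coupling, ct.columns.tolist(), mrna.columns.tolist()
    )
    return SyntheticCohort(
        params=params,
        pedigree=ped,
        phenotypes=phen,
        phenotype_truth=phen_truth,
        ct=ct,
        mirna_truth=mirna_truth,
        mrna=mrna,
        cells=cells,
        coupling=coupling,
        mirna_seqs=mirna_seqs,
        region_seqs=region_seqs,
        planted_sites=planted,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
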