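"""Synthetic pedigreed populations with longitudinal feeding-station records.

The generator emulates a finishing-pig test barn: pigs housed ~15 per pen,
one daily summary record per animal between 95 and 155 days of age with
weight (kg), feed intake (g/d), feeder-visit duration (s/d) and number of
visits. Growth follows an individual Gompertz curve whose parameters carry
additive genetic and environmental variation; the day-to-day residual
standard deviation around the curve is itself heritable on the log-variance
scale (an exponential model, ``sd_i = exp((mu_v + v_i)/2)`` with ``v``
additive). Perturbation events depress feed intake first and weight gain
second; technical artifacts (single-day spikes, inflated adaptation-phase
weights, missing days, gross errors) can be injected on top with a ledger
of every corrupted cell so that quality-control sensitivity/specificity can
be scored exactly.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_pedigree",
    "simulate_genetic_values",
    "simulate_growth_and_feeding",
    "inject_artifacts",
    "simulate_genotypes",
    "simulate_dataset",
    "simulate_trait_pair",
    "gompertz_curve",
]

#: artifact kinds that corrupt a recorded weight cell (scored against QC)
WEIGHT_ARTIFACTS = ("spike", "adaptation", "gross")


def gompertz_curve(A, B, k, t):
    """Increasing Gompertz mean curve ``A * exp(-B * exp(-k*t))``."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-B * np.exp(-k * t))


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic population.

    Defaults mirror the emulated test-barn: ~15 pigs/pen, a 60-day finishing
    window (95-155 d), near-linear growth (mean curve runs 46.5 -> ~109 kg,
    ADG ~= 1.04 kg/d), lowly heritable curve parameters and a heritable
    log-residual-variance ``v``.
    """

    # pedigree
    n_sires: int = 8
    n_dams: int = 40
    offspring_per_litter: int = 3
    n_litters: int | None = None  # default: one litter per dam
    # housing
    pigs_per_pen: int = 15
    n_farms: int = 2
    n_cg: int = 8
    sex_ratio: float = 0.5  # proportion male
    # recording window (inclusive ages, days)
    age_range: tuple[int, int] = (95, 155)
    # growth-curve population distribution: (A kg, B unitless, k per-day)
    curve_mean: tuple[float, float, float] = (220.0, 6.0, 0.0135)
    curve_sd: tuple[float, float, float] = (25.0, 0.8, 0.002)
    curve_corr: tuple = ((1.0, -0.4, -0.7), (-0.4, 1.0, 0.8), (-0.7, 0.8, 1.0))
    h2_curve: tuple[float, float, float] = (0.07, 0.09, 0.10)
    # log residual variance of daily weight (kg^2 scale): sd_i = exp((mu_v+v_i)/2)
    # default matches the ~0.5 kg accuracy of feeding-station scales
    mu_v: float = -1.4
    sigma2_av: float = 0.05
    # contemporary group / fixed-effect multipliers on the growth curve
    cg_sd: float = 0.04
    sex_effect: float = 0.03
    farm_effect: float = 0.02
    # feeding model (g/d): FI = feed_gain_coef * gain_g + feed_maint_coef * W_kg
    feed_gain_coef: float = 1.4
    feed_maint_coef: float = 11.2
    feed_noise_sd: float = 150.0
    feed_per_gain: float = 2.24  # g feed per g gain used for perturbation deficits
    # visit behaviour
    dur_mean: float = 4200.0
    dur_between_sd: float = 800.0
    dur_noise_sd: float = 900.0
    visits_mean: float = 10.0
    visits_between_sd: float = 3.0
    # perturbations: Poisson onsets, Beta-distributed depths
    perturbation_rate: float = 0.6  # events per animal per window
    perturbation_depth: float = 0.5  # mean fractional feed-intake drop
    perturbation_duration: int = 5  # days
    # technical artifacts (probabilities; 'adaptation' is per animal)
    artifact_rates: dict = field(
        default_factory=lambda: {
            "spike": 0.01,       # per animal-day
            "adaptation": 0.15,  # per pen
            "missing": 0.02,     # per animal-day
            "gross": 0.002,      # per animal-day
        }
    )
    n_snps: int = 500
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sires, self.n_dams, self.offspring_per_litter) <= 0:
            raise ValueError("pedigree counts must be positive")
        if self.n_litters is not None and self.n_litters <= 0:
            raise ValueError("n_litters must be positive")
        if min(self.pigs_per_pen, self.n_farms, self.n_cg) <= 0:
            raise ValueError("housing counts must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 < self.perturbation_depth <= 1.0:
            raise ValueError("perturbation_depth must lie in (0, 1]")
        if self.perturbation_duration < 1:
            raise ValueError("perturbation_duration must be >= 1 day")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range start must precede end")
        if self.sigma2_av < 0:
            raise ValueError("sigma2_av must be non-negative")
        if any(not 0.0 <= h <= 1.0 for h in self.h2_curve):
            raise ValueError("h2_curve entries must lie in [0, 1]")
        if any(not 0.0 <= r <= 1.0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must lie in [0, 1]")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class SimResult:
    """Bundle returned by :func:`simulate_dataset`."""

    records: pd.DataFrame
    pedigree: pd.DataFrame
    truth: pd.DataFrame
    events: pd.DataFrame
    anchors: pd.DataFrame
    artifact_ledger: pd.DataFrame
    clean_records: pd.DataFrame
    genotypes: pd.DataFrame | None = None
    allele_freqs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pedigree and housing


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Founder sires/dams plus one offspring generation with housing metadata.

    Returns a parents-before-offspring DataFrame with columns id, sire, dam
    (0 = unknown), sex, farm, compartment, pen, cg, birth_date, entry_date,
    litter. Litters map to contemporary groups (farm x compartment x entry
    batch); offspring within a contemporary group are packed into pens of
    ``pigs_per_pen``.
    """
    cfg.validate()
    rng = cfg.rng(1)
    n_litters = cfg.n_litters if cfg.n_litters is not None else cfg.n_dams
    if n_litters < cfg.n_dams:
        raise ValueError("n_litters must be >= n_dams (each dam farrows at least once)")

    sires = np.arange(1, cfg.n_sires + 1)
    dams = np.arange(cfg.n_sires + 1, cfg.n_sires + cfg.n_dams + 1)
    rows = []
    for s in sires:
        rows.append(dict(id=s, sire=0, dam=0, sex="M"))
    for d in dams:
        rows.append(dict(id=d, sire=0, dam=0, sex="F"))

    # litters: dams round-robin, sires assigned in shuffled blocks
    litter_dam = dams[np.arange(n_litters) % cfg.n_dams]
    litter_sire = sires[rng.permutation(np.arange(n_litters) % cfg.n_sires)]
    litter_cg = np.arange(n_litters) % cfg.n_cg
    base = date(2020, 1, 6)
    next_id = cfg.n_sires + cfg.n_dams + 1
    for lit in range(n_litters):
        birth = base + timedelta(days=int(7 * (litter_cg[lit] + 1)))
        for _ in range(cfg.offspring_per_litter):
            rows.append(
                dict(
                    id=next_id,
                    sire=int(litter_sire[lit]),
                    dam=int(litter_dam[lit]),
                    sex="M" if rng.random() < cfg.sex_ratio else "F",
                    litter=lit,
                    cg=int(litter_cg[lit]),
                    birth_date=pd.Timestamp(birth),
                    entry_date=pd.Timestamp(birth + timedelta(days=70)),
                )
            )
            next_id += 1
    ped = pd.DataFrame(rows)

    off = ped["sire"] != 0
    # farm/compartment derive from the contemporary group
    ped.loc[off, "farm"] = (ped.loc[off, "cg"] % cfg.n_farms).astype(int)
    ped.loc[off, "compartment"] = (ped.loc[off, "cg"] // cfg.n_farms).astype(int)
    # pens packed within contemporary group
    pen_labels = np.full(off.sum(), -1)
    offspring_idx = np.flatnonzero(off.to_numpy())
    cg_vals = ped.loc[off, "cg"].to_numpy()
    pen_no = 0
    for g in np.unique(cg_vals):
        members = offspring_idx[cg_vals == g]
        for start in range(0, len(members), cfg.pigs_per_pen):
            chunk = members[start : start + cfg.pigs_per_pen]
            pen_labels[np.searchsorted(offspring_idx, chunk)] = pen_no
            pen_no += 1
    ped.loc[off, "pen"] = pen_labels
    return ped


# ---------------------------------------------------------------------------
# genetic values


def _mendelian_bv(ped: pd.DataFrame, cov: np.ndarray, rng) -> np.ndarray:
    """Recursive mendelian sampling of multivariate breeding values.

    Founders ~ N(0, cov); offspring = midparent + N(0, cov/2). Inbreeding in
    the mendelian-sampling variance is ignored (additive model only).
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n, d = len(ped), cov.shape[0]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(d))
    idx = {a: i for i, a in enumerate(ped["id"])}
    bv = np.zeros((n, d))
    z = rng.standard_normal((n, d))
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    for i in range(n):
        if sires[i] == 0 and dams[i] == 0:
            bv[i] = z[i] @ chol.T
        else:
            mid = 0.5 * (bv[idx[sires[i]]] + bv[idx[dams[i]]])
            bv[i] = mid + np.sqrt(0.5) * (z[i] @ chol.T)
    return bv


def simulate_genetic_values(ped: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Attach true curve parameters, breeding values and perturbation-scale v.

    Curve parameters (A, B, k) receive correlated additive and environmental
    parts matching ``h2_curve``; ``v`` (log residual variance of daily weight)
    is purely additive with variance ``sigma2_av``. Contemporary group, sex
    and farm act as multipliers on the whole curve (equivalently on A).
    """
    cfg.validate()
    rng = cfg.rng(2)
    corr = np.asarray(cfg.curve_corr, dtype=float)
    sd = np.asarray(cfg.curve_sd, dtype=float)
    h2 = np.asarray(cfg.h2_curve, dtype=float)
    cov_a = np.outer(np.sqrt(h2) * sd, np.sqrt(h2) * sd) * corr
    cov_e = np.outer(np.sqrt(1 - h2) * sd, np.sqrt(1 - h2) * sd) * corr

    truth = ped.copy()
    bv_curve = _mendelian_bv(ped, cov_a, rng)
    env_curve = rng.multivariate_normal(np.zeros(3), cov_e, size=len(ped), method="cholesky")
    bv_v = _mendelian_bv(ped, [[cfg.sigma2_av]], rng)[:, 0] if cfg.sigma2_av > 0 else np.zeros(len(ped))

    mean = np.asarray(cfg.curve_mean)
    params = mean + bv_curve + env_curve
    # keep parameters in the valid (positive, growing) region
    params[:, 0] = np.clip(params[:, 0], 80.0, None)
    params[:, 1] = np.clip(params[:, 1], 1.5, None)
    params[:, 2] = np.clip(params[:, 2], 2e-3, None)

    truth[["bv_A", "bv_B", "bv_k"]] = bv_curve
    truth["bv_v"] = bv_v
    truth["v"] = bv_v  # purely additive
    truth[["true_A", "true_B", "true_k"]] = params

    off = truth["sire"] != 0
    cg_eff = rng.normal(0.0, cfg.cg_sd, size=cfg.n_cg)
    mult = np.ones(len(truth))
    cg_idx = truth.loc[off, "cg"].astype(int).to_numpy()
    mult[off.to_numpy()] += cg_eff[cg_idx]
    mult[off.to_numpy()] += np.where(truth.loc[off, "sex"].to_numpy() == "M", cfg.sex_effect, 0.0)
    mult[off.to_numpy()] += cfg.farm_effect * truth.loc[off, "farm"].to_numpy()
    truth["curve_mult"] = mult
    truth["true_A_eff"] = truth["true_A"] * truth["curve_mult"]
    return truth


# ---------------------------------------------------------------------------
# longitudinal records


def _draw_events(cfg: SimConfig, rng, lo: int, hi: int) -> list[tuple[int, int, float]]:
    n = rng.poisson(cfg.perturbation_rate)
    events = []
    mu = cfg.perturbation_depth
    beta_b = max(2.0 * (1.0 - mu) / mu, 1e-3)
    for _ in range(n):
        onset = int(rng.integers(lo, hi + 1))
        depth = float(np.clip(rng.beta(2.0, beta_b), 0.02, 1.0))
        events.append((onset, cfg.perturbation_duration, depth))
    return events


def simulate_growth_and_feeding(truth: pd.DataFrame, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily records for every offspring animal, plus the perturbation-event table.

    Observed weight = multiplier-scaled Gompertz curve minus the cumulative
    perturbation deficit plus iid N(0, exp(mu_v + v_i)) noise. Feed intake is
    a maintenance-plus-gain linear rule scaled by (1 - depth) during
    perturbations; the lost feed converts to a permanent weight-gain deficit
    at ``feed_per_gain``. Visit duration/count vary around animal-level means.
    """
    cfg.validate()
    rng = cfg.rng(3)
    lo, hi = cfg.age_range
    ages = np.arange(lo, hi + 1)
    nt = len(ages)

    rec_rows = []
    ev_rows = []
    off = truth[truth["sire"] != 0]
    for row in off.itertuples():
        A = row.true_A * row.curve_mult
        B, k = row.true_B, row.true_k
        if min(A, B, k) <= 0:
            raise ValueError("growth-curve parameters must be positive")
        w_exp = gompertz_curve(A, B, k, ages)
        w_prev = gompertz_curve(A, B, k, ages - 1)
        gain_g = (w_exp - w_prev) * 1000.0
        fi_exp = cfg.feed_gain_coef * gain_g + cfg.feed_maint_coef * w_exp

        depth_t = np.zeros(nt)
        for onset, dur, depth in _draw_events(cfg, rng, lo, hi):
            sel = (ages >= onset) & (ages < onset + dur)
            depth_t[sel] = np.maximum(depth_t[sel], depth)
            ev_rows.append(dict(animal_id=row.id, onset_d=onset, duration_d=dur, depth=depth))

        fi_deficit = depth_t * fi_exp
        fi_obs = fi_exp - fi_deficit + rng.normal(0.0, cfg.feed_noise_sd * np.exp(row.v / 2.0), nt)
        fi_obs = np.clip(fi_obs, 0.0, None)
        deficit_kg = np.cumsum(fi_deficit / cfg.feed_per_gain) / 1000.0
        sd_w = np.exp((cfg.mu_v + row.v) / 2.0)
        w_obs = w_exp - deficit_kg + rng.normal(0.0, sd_w, nt)

        dur_mean_i = max(cfg.dur_mean + rng.normal(0.0, cfg.dur_between_sd), 600.0)
        dur_obs = dur_mean_i * (1.0 - 0.8 * depth_t) + rng.normal(
            0.0, cfg.dur_noise_sd * np.exp(row.v / 2.0), nt
        )
        dur_obs = np.clip(dur_obs, 0.0, None)
        lam = max(cfg.visits_mean + rng.normal(0.0, cfg.visits_between_sd), 1.0)
        nvis = rng.poisson(lam * (1.0 - 0.5 * depth_t)).astype(float)

        rec_rows.append(
            pd.DataFrame(
                dict(
                    animal_id=row.id,
                    age_d=ages,
                    weight_kg=w_obs,
                    fi_g_per_d=fi_obs,
                    dur_s_per_d=dur_obs,
                    nvisits_per_d=nvis,
                    pen=int(row.pen),
                    compartment=int(row.compartment),
                    farm=int(row.farm),
                    cg=int(row.cg),
                    sex=row.sex,
                    birth_date=row.birth_date,
                    entry_date=row.entry_date,
                )
            )
        )
    records = pd.concat(rec_rows, ignore_index=True)
    events = pd.DataFrame(ev_rows, columns=["animal_id", "onset_d", "duration_d", "depth"])
    return records, events


def simulate_anchors(truth: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Technician weights at birth, 14 d and start/end of test from the true curve."""
    rng = cfg.rng(4)
    off = truth[truth["sire"] != 0]
    anchor_ages = np.array([0, 14, 81, 161])
    rows = []
    for row in off.itertuples():
        w = gompertz_curve(row.true_A * row.curve_mult, row.true_B, row.true_k, anchor_ages)
        w = np.clip(w + rng.normal(0.0, 0.3, len(anchor_ages)), 0.05, None)
        for a, wk in zip(anchor_ages, w):
            rows.append(dict(animal_id=row.id, age_d=int(a), weight_kg=float(wk), source="manual"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artifacts


def inject_artifacts(records: pd.DataFrame, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt records with the configured technical-error modes.

    Modes: single-day weight spikes (> 3 kg off curve), inflated weights in
    the first days after entry (adaptation phase, decaying inflation), missing
    days (rows dropped) and gross errors (< 10 kg or > 160 kg). The returned
    ledger lists every corrupted weight cell (animal_id, age_d, kind,
    original, corrupted); dropped rows are listed with kind 'missing'.
    """
    cfg.validate()
    rates = cfg.artifact_rates
    rng = cfg.rng(5)
    out = records.copy().reset_index(drop=True)
    ledger = []

    weight = out["weight_kg"].to_numpy().copy()
    n = len(out)
    corrupted = np.zeros(n, dtype=bool)

    # adaptation phase: a pen-level phenomenon — penmates enter the station
    # together in the first days, so the scale reads more than one pig
    if rates.get("adaptation", 0) > 0:
        for pen, pen_grp in out.groupby("pen", sort=False):
            if rng.random() >= rates["adaptation"]:
                continue
            for aid, grp in pen_grp.groupby("animal_id", sort=False):
                if rng.random() >= 0.7:
                    continue
                idx = grp.index.to_numpy()[np.argsort(grp["age_d"].to_numpy())]
                # short residual episodes: the learning curve proper has
                # faded by the start of the standard age window
                ndays = int(rng.integers(2, 4))
                # a second pig on the scale roughly doubles the reading at
                # first; interference decays but stays substantial
                infl0 = rng.uniform(0.7, 1.1)
                for j, i in enumerate(idx[:ndays]):
                    factor = 1.0 + max(infl0 * (1.0 - j / ndays), 0.15)
                    new = weight[i] * factor
                    ledger.append(
                        dict(animal_id=aid, age_d=int(out.at[i, "age_d"]), column="weight_kg",
                             kind="adaptation", original=weight[i], corrupted=new)
                    )
                    weight[i] = new
                    corrupted[i] = True

    # single-day spikes
    if rates.get("spike", 0) > 0:
        hit = np.flatnonzero((rng.random(n) < rates["spike"]) & ~corrupted)
        for i in hit:
            delta = rng.uniform(5.0, 25.0) * rng.choice([-1.0, 1.0])
            new = max(weight[i] + delta, 0.5)
            ledger.append(
                dict(animal_id=out.at[i, "animal_id"], age_d=int(out.at[i, "age_d"]),
                     column="weight_kg", kind="spike", original=weight[i], corrupted=new)
            )
            weight[i] = new
            corrupted[i] = True

    # gross errors outside the plausible [10, 160] kg range
    if rates.get("gross", 0) > 0:
        hit = np.flatnonzero((rng.random(n) < rates["gross"]) & ~corrupted)
        for i in hit:
            new = rng.uniform(0.5, 9.5) if rng.random() < 0.5 else rng.uniform(161.0, 350.0)
            ledger.append(
                dict(animal_id=out.at[i, "animal_id"], age_d=int(out.at[i, "age_d"]),
                     column="weight_kg", kind="gross", original=weight[i], corrupted=new)
            )
            weight[i] = new
            corrupted[i] = True

    out["weight_kg"] = weight

    # missing days: whole row dropped
    drop = np.zeros(n, dtype=bool)
    if rates.get("missing", 0) > 0:
        drop = rng.random(n) < rates["missing"]
        for i in np.flatnonzero(drop):
            ledger.append(
                dict(animal_id=out.at[i, "animal_id"], age_d=int(out.at[i, "age_d"]),
                     column=None, kind="missing", original=np.nan, corrupted=np.nan)
            )
        out = out.loc[~drop].reset_index(drop=True)

    ledger_df = pd.DataFrame(
        ledger, columns=["animal_id", "age_d", "column", "kind", "original", "corrupted"]
    )
    return out, ledger_df


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(ped: pd.DataFrame, cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-dropped SNP dosages (0/1/2) for every pedigree animal.

    Founder allele frequencies ~ Uniform(0.05, 0.95); offspring inherit one
    random allele per parent per locus.
    """
    cfg.validate()
    rng = cfg.rng(6)
    m = cfg.n_snps
    freqs = rng.uniform(0.05, 0.95, m)
    idx = {a: i for i, a in enumerate(ped["id"])}
    n = len(ped)
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    for i in range(n):
        if sires[i] == 0 and dams[i] == 0:
            alleles[i] = (rng.random((m, 2)) < freqs[:, None]).astype(np.int8)
        else:
            s, d = idx[sires[i]], idx[dams[i]]
            pick_s = rng.integers(0, 2, m)
            pick_d = rng.integers(0, 2, m)
            cols = np.arange(m)
            alleles[i, :, 0] = alleles[s, cols, pick_s]
            alleles[i, :, 1] = alleles[d, cols, pick_d]
    dosages = alleles.sum(axis=2).astype(np.int8)
    geno = pd.DataFrame(dosages, index=ped["id"].to_numpy(),
                        columns=[f"snp{j}" for j in range(m)])
    return geno, freqs


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(cfg: SimConfig, genotypes: bool = False) -> SimResult:
    """Run the full generator: pedigree, genetics, records, artifacts, anchors."""
    ped = simulate_pedigree(cfg)
    truth = simulate_genetic_values(ped, cfg)
    clean, events = simulate_growth_and_feeding(truth, cfg)
    records, ledger = inject_artifacts(clean, cfg)
    anchors = simulate_anchors(truth, cfg)
    pedigree = ped[["id", "sire", "dam"]].copy()
    geno, freqs = (None, None)
    if genotypes:
        geno, freqs = simulate_genotypes(ped, cfg)
    return SimResult(
        records=records,
        pedigree=pedigree,
        truth=truth,
        events=events,
        anchors=anchors,
        artifact_ledger=ledger,
        clean_records=clean,
        genotypes=geno,
        allele_freqs=freqs,
    )


def simulate_genomic_trait(
    genotypes: pd.DataFrame,
    freqs: np.ndarray,
    h2: float,
    seed: int = 0,
    var_p: float = 1.0,
) -> pd.DataFrame:
    """One phenotype whose breeding values are sums of SNP effects.

    Effects are drawn iid normal with total additive variance ``h2 * var_p``
    on centred dosages, so realized genomic sharing (not just pedigree
    expectation) carries the signal — the setting in which single-step
    genomic evaluation should out-predict pedigree BLUP.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 98)))
    p = np.asarray(freqs, dtype=float)
    Z = genotypes.to_numpy(dtype=float) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    beta = rng.normal(0.0, np.sqrt(h2 * var_p / denom), size=Z.shape[1])
    bv = Z @ beta
    e = rng.normal(0.0, np.sqrt((1.0 - h2) * var_p), size=len(bv))
    return pd.DataFrame({"animal": genotypes.index, "y": bv + e, "bv": bv})


def simulate_trait_pair(
    ped: pd.DataFrame,
    h2_1: float,
    h2_2: float,
    rg: float,
    seed: int = 0,
    var_p: tuple[float, float] = (1.0, 1.0),
    cg: pd.Series | None = None,
    sigma2_cg: float = 0.0,
) -> pd.DataFrame:
    """Two phenotypes with specified heritabilities and genetic correlation.

    Breeding values are drawn by mendelian sampling down the pedigree with the
    implied 2x2 genetic covariance; residuals are independent between traits
    (the residual structure the animal models assume). Intended for variance-
    component and cross-validation recovery tests with known ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    sa = np.array([np.sqrt(h2_1 * var_p[0]), np.sqrt(h2_2 * var_p[1])])
    G0 = np.array([[sa[0] ** 2, rg * sa[0] * sa[1]], [rg * sa[0] * sa[1], sa[1] ** 2]])
    bv = _mendelian_bv(ped, G0, rng)
    res_var = np.array([var_p[0] - G0[0, 0] - sigma2_cg, var_p[1] - G0[1, 1] - sigma2_cg])
    if np.any(res_var < 0):
        raise ValueError("residual variance would be negative")
    se = np.sqrt(res_var)
    out = pd.DataFrame({"animal": ped["id"].to_numpy()})
    e = rng.standard_normal((len(ped), 2)) * se
    cg_eff = np.zeros((len(ped), 2))
    if cg is not None and sigma2_cg > 0:
        levels = pd.unique(cg.dropna())
        eff = rng.normal(0.0, np.sqrt(sigma2_cg), size=(len(levels), 2))
        lut = {g: eff[i] for i, g in enumerate(levels)}
        cg_eff = np.array([lut.get(g, (0.0, 0.0)) for g in cg.reindex(ped["id"]).to_numpy()])
    out["y1"] = bv[:, 0] + e[:, 0] + cg_eff[:, 0]
    out["y2"] = bv[:, 1] + e[:, 1] + cg_eff[:, 1]
    out["bv1"] = bv[:, 0]
    out["bv2"] = bv[:, 1]
    return out
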