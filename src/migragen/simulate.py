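"""Synthetic cohort generator with persisted ground truth.

Emulates the cohort design the downstream analyses assume: ~190 diploid
individuals admixed between two ancestral populations (Balding–Nichols
divergence, so the F_ST estimator has a known target), ~28K biallelic
SNPs, a small set of causal loci acting on a migration liability, and
one-fix-per-day year-long GPS tracks for migrant and resident animals.

The liability model is the simplest generative model consistent with
both the binary (movement-model classification) and continuous (range
overlap) phenotypes analysed downstream:

    l_i = intercept + ancestry_effect * Q_i,north
          + sum_c causal_effect * (g_ic - 2 f_c)
    P(migrant_i) = logistic(l_i)

Causal dosages are centred at their expected value so the intercept
controls the baseline migrant fraction independently of allele
frequencies.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_ancestral_freqs",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_track",
    "simulate_dataset",
    "write_fixture_set",
]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults encode the reference cohort design: 190 individuals from
    two ancestral clusters differentiated at F_ST ~ 0.017, 28K SNPs,
    57 causal loci, a logistic ancestry effect of 1.81 on the migrant
    liability, ~80% migrants, 50 km seasonal separation, spring
    departure mid-May and autumn return mid-October, daily fixes.
    """

    n_individuals: int = 190
    n_snps: int = 28_000
    k_true: int = 2
    fst_divergence: tuple[float, ...] = (0.017, 0.017)
    q_alpha: float = 0.5
    n_causal: int = 57
    causal_effect: float = 0.2
    ancestry_effect: float = 1.81
    intercept: float = 0.55
    migration_distance_km: float = 50.0
    departure_day: float = 135.0
    return_day: float = 290.0
    transition_sd_days: float = 10.0
    step_sd_km: float = 5.0
    n_years: int = 1
    missing_fix_rate: float = 0.05
    n_ecotypes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.fst_divergence):
            self.fst_divergence = tuple([float(self.fst_divergence)] * self.k_true)
        else:
            self.fst_divergence = tuple(float(f) for f in self.fst_divergence)
        for name in ("n_individuals", "n_snps", "k_true", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_causal < 0 or self.n_causal > self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        if len(self.fst_divergence) != self.k_true:
            raise ValueError("fst_divergence must have one value per population")
        for f in self.fst_divergence:
            if not np.isfinite(f) or not (0.0 < f < 1.0):
                raise ValueError(f"fst_divergence values must lie in (0,1); got {f}")
        if not (0.0 <= self.missing_fix_rate < 1.0):
            raise ValueError("missing_fix_rate must lie in [0,1)")
        if self.migration_distance_km <= 0:
            raise ValueError("migration_distance_km must be positive")


@dataclass
class SimulatedTruth:
    """Ground truth persisted alongside a synthetic cohort."""

    q: np.ndarray                    # (n, k_true), rows sum to 1
    migrant: np.ndarray              # (n,) 0/1
    io: np.ndarray                   # (n,) directly simulated overlap index
    causal_indices: np.ndarray       # unique, in [0, n_snps)
    causal_effects: np.ndarray
    ecotype: np.ndarray              # (n,) string labels
    winter_centers: np.ndarray       # (n, 2) projected km
    summer_centers: np.ndarray       # (n, 2) projected km

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if len(np.unique(self.causal_indices)) != len(self.causal_indices):
            raise ValueError("causal indices must be unique")


def simulate_ancestral_freqs(n_snps, k_true, fst_divergence, seed):
    """Balding–Nichols ancestral allele frequencies, (k_true, n_snps).

    A base frequency p ~ U(0.05, 0.95) is drawn per locus; population k
    draws its frequency from Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), so
    population frequencies have mean p and variance F_k p(1-p).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    fst = np.atleast_1d(np.asarray(fst_divergence, dtype=float))
    if fst.size == 1:
        fst = np.repeat(fst, k_true)
    if fst.size != k_true:
        raise ValueError("need one divergence value per population")
    if not np.all(np.isfinite(fst)) or np.any(fst <= 0) or np.any(fst >= 1):
        raise ValueError("divergence values must be finite and in (0,1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    freqs = np.empty((k_true, n_snps))
    for k in range(k_true):
        scale = (1.0 - fst[k]) / fst[k]
        freqs[k] = rng.beta(p * scale, (1.0 - p) * scale)
    # Beta draws can hit 0/1 in floating point at extreme shapes
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def simulate_admixture_q(n_individuals, k_true, q_alpha, seed):
    """Per-individual admixture proportions from a symmetric Dirichlet."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet([q_alpha] * k_true, size=n_individuals)


def simulate_genotypes(freqs, q, seed):
    """Binomial(2, pi) genotypes with pi_ij = sum_k Q_ik F_kj; no missing."""
    freqs = np.asarray(freqs, dtype=float)
    q = np.asarray(q, dtype=float)
    if q.shape[1] != freqs.shape[0]:
        raise ValueError(
            f"dimension mismatch: Q has {q.shape[1]} populations, "
            f"F has {freqs.shape[0]}"
        )
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("Q rows must sum to 1 within 1e-8")
    rng = np.random.default_rng(seed)
    pi = q @ freqs
    return rng.binomial(2, pi).astype(np.int8)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_phenotypes(genotypes, truth, config, seed=None):
    """Draw migrant status and range-overlap index from the liability model.

    Returns ``(migrant, io)``.  IO is drawn Beta(2,8) for migrants and
    Beta(8,2) for residents (means 0.2 / 0.8): migrants separate their
    seasonal ranges, residents keep them overlapping.
    """
    g = np.asarray(genotypes, dtype=float)
    idx = np.asarray(truth.causal_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= g.shape[1]):
        raise ValueError("causal indices out of range")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    liab = np.full(g.shape[0], float(config.intercept))
    liab += config.ancestry_effect * truth.q[:, 0]
    if idx.size:
        dos = g[:, idx]
        centred = dos - dos.mean(axis=0, keepdims=True)
        liab += centred @ np.asarray(truth.causal_effects, dtype=float)
    migrant = (rng.uniform(size=g.shape[0]) < _logistic(liab)).astype(int)
    io = np.where(migrant == 1, rng.beta(2, 8, size=g.shape[0]),
                  rng.beta(8, 2, size=g.shape[0]))
    return migrant, io


def simulate_track(animal_id, status, config, seed, start_year=2015,
                   winter_center=(0.0, 0.0), summer_center=None):
    """Daily GPS fixes for one animal as a telemetry DataFrame.

    Positions are the active seasonal centre plus isotropic Gaussian
    noise (sd ``step_sd_km``).  Residents hold a single centre; migrants
    move between winter and summer centres on a logistic schedule around
    jittered departure/return days, with at least 30 days on the second
    range.  Fixes are daily at 12:00, dropped at ``missing_fix_rate``.
    """
    if config.migration_distance_km <= 0:
        raise ValueError("migration_distance_km must be positive")
    if config.n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    winter_center = np.asarray(winter_center, dtype=float)
    if summer_center is None:
        summer_center = winter_center + np.array([0.0, config.migration_distance_km])
    summer_center = np.asarray(summer_center, dtype=float)

    dates = pd.date_range(
        f"{start_year}-01-01 12:00", periods=365 * config.n_years, freq="D"
    )
    t = np.arange(len(dates), dtype=float)
    if status == "migrant":
        w = np.zeros(len(dates))
        scale = 3.0  # days; transition steepness of the centre switch
        for year in range(config.n_years):
            dep = config.departure_day + rng.normal(0, config.transition_sd_days)
            ret = config.return_day + rng.normal(0, config.transition_sd_days)
            # a migrant must hold the second range >= 30 days (rho constraint)
            ret = max(ret, dep + 30 + 4 * scale)
            off = 365.0 * year
            w += _logistic((t - (off + dep)) / scale) - _logistic(
                (t - (off + ret)) / scale
            )
        w = np.clip(w, 0.0, 1.0)
    elif status == "resident":
        w = np.zeros(len(dates))
    else:
        raise ValueError(f"unknown status {status!r}")

    centers = np.outer(1 - w, winter_center) + np.outer(w, summer_center)
    xy = centers + rng.normal(0, config.step_sd_km, size=centers.shape)
    keep = rng.uniform(size=len(dates)) >= config.missing_fix_rate
    df = pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": dates[keep],
            "x_km": xy[keep, 0],
            "y_km": xy[keep, 1],
            "crs": "SYNTH-AEQA-KM",
        }
    )
    return df


def _assign_ecotypes(q_north, n_ecotypes, rng):
    """Ecological groupings loosely tracking ancestry, with overlap."""
    noisy = q_north + rng.normal(0, 0.15, size=q_north.shape)
    edges = np.quantile(noisy, np.linspace(0, 1, n_ecotypes + 1)[1:-1])
    labels = np.digitize(noisy, edges)
    names = np.array([f"ecotype_{chr(ord('A') + i)}" for i in range(n_ecotypes)])
    return names[labels]


def simulate_dataset(config):
    """Full synthetic cohort: genotypes, truth and per-animal telemetry.

    Returns ``(genotypes, truth, telemetry)`` where telemetry is one
    concatenated DataFrame in the telemetry CSV schema.  Deterministic
    given ``config.seed``; independent substreams per component.
    """
    base = np.random.SeedSequence(config.seed)
    s_freq, s_q, s_geno, s_phen, s_track, s_eco = [
        int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(6)
    ]
    freqs = simulate_ancestral_freqs(
        config.n_snps, config.k_true, config.fst_divergence, s_freq
    )
    q = simulate_admixture_q(config.n_individuals, config.k_true,
                             config.q_alpha, s_q)
    genotypes = simulate_genotypes(freqs, q, s_geno)
    rng = np.random.default_rng(s_phen)
    causal_idx = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    causal_idx.sort()
    effects = np.full(config.n_causal, config.causal_effect)
    eco_rng = np.random.default_rng(s_eco)
    truth = SimulatedTruth(
        q=q,
        migrant=np.zeros(config.n_individuals, dtype=int),
        io=np.zeros(config.n_individuals),
        causal_indices=causal_idx,
        causal_effects=effects,
        ecotype=_assign_ecotypes(q[:, 0], config.n_ecotypes, eco_rng),
        winter_centers=np.zeros((config.n_individuals, 2)),
        summer_centers=np.zeros((config.n_individuals, 2)),
    )
    truth.migrant, truth.io = simulate_phenotypes(genotypes, truth, config, s_phen)

    track_rng = np.random.SeedSequence(s_track).spawn(config.n_individuals)
    frames = []
    for i in range(config.n_individuals):
        # spread winter ranges so animals are distinguishable on a map
        wrng = np.random.default_rng(int(track_rng[i].generate_state(1)[0] % 2**31))
        wc = wrng.uniform(-200, 200, size=2)
        status = "migrant" if truth.migrant[i] else "resident"
        df = simulate_track(
            f"animal_{i:03d}", status, config,
            seed=int(track_rng[i].generate_state(2)[1] % 2**31),
            winter_center=wc,
        )
        truth.winter_centers[i] = wc
        truth.summer_centers[i] = (
            wc + np.array([0.0, config.migration_distance_km])
            if truth.migrant[i]
            else wc
        )
        frames.append(df)
    telemetry = pd.concat(frames, ignore_index=True)
    return genotypes, truth, telemetry


def _write_vcf(path, genotypes, chrom=None, pos=None):
    """Write a minimal GT-only biallelic VCF v4.2 (text, deterministic)."""
    g = np.asarray(genotypes)
    n, m = g.shape
    if chrom is None:
        per_chrom = max(1, m // 10)
        chrom = np.array([f"chr{j // per_chrom + 1}" for j in range(m)])
    if pos is None:
        pos = np.zeros(m, dtype=int)
        counter = {}
        for j, c in enumerate(chrom):
            counter[c] = counter.get(c, 0) + 100
            pos[j] = counter[c]
    samples = [f"animal_{i:03d}" for i in range(n)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(m):
            gts = "\t".join(
                gt_map.get(int(v), "./.") if v == v else "./." for v in g[:, j]
            )
            fh.write(
                f"{chrom[j]}\t{pos[j]}\tsnp_{j:06d}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_fixture_set(config, out_dir):
    """Write VCF, telemetry CSV, truth TSV and a config echo to disk.

    Byte-identical across runs at a fixed seed.  Returns a dict of paths.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        genotypes, truth, telemetry = simulate_dataset(config)
        paths = {
            "vcf": out / "genotypes.vcf",
            "telemetry": out / "telemetry.csv",
            "truth": out / "truth.tsv",
            "config": out / "config.yaml",
        }
        _write_vcf(paths["vcf"], genotypes)
        telemetry = telemetry.copy()
        telemetry["timestamp"] = telemetry["timestamp"].dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        telemetry["x_km"] = telemetry["x_km"].map(lambda v: f"{v:.6f}")
        telemetry["y_km"] = telemetry["y_km"].map(lambda v: f"{v:.6f}")
        telemetry.to_csv(paths["telemetry"], index=False)
        tdf = pd.DataFrame(
            {
                "animal_id": [f"animal_{i:03d}" for i in range(config.n_individuals)],
                "migrant": truth.migrant,
                "io_true": [f"{v:.6f}" for v in truth.io],
                "ecotype": truth.ecotype,
            }
        )
        for k in range(config.k_true):
            tdf[f"q{k + 1}"] = [f"{v:.6f}" for v in truth.q[:, k]]
        tdf["causal_indices"] = ""
        tdf.loc[0, "causal_indices"] = ",".join(map(str, truth.causal_indices))
        tdf.to_csv(paths["truth"], sep="\t", index=False)
        cfg = dataclasses.asdict(config)
        cfg["fst_divergence"] = list(config.fst_divergence)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}
    except OSError as exc:
        raise OSError(f"failed to write fixture set under {out}: {exc}") from exc


def file_sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
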