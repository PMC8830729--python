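"""End-to-end pipeline orchestration with deterministic stage outputs.

Stages run in order telemetry/movement -> popgen -> association ->
ancestry, exchanging plain TSV/JSON files; each stage writes a manifest
with SHA-256 hashes of its inputs and the config echo, so a rerun with
unchanged inputs is byte-identical.  Every numeric threshold comes from
the PipelineConfig (defaults are the analysis-standard values quoted
throughout the module docstrings), never from stage code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from migragen import (
    telemetry as tele,
    movement as mv,
    popgen as pg,
    association as assoc,
    ancestry as anc,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("movement", "popgen", "assoc", "ancestry")


@dataclass
class PipelineConfig:
    """All pipeline paths, thresholds and the master seed."""

    telemetry: str | None = None
    vcf: str | None = None
    gene_table: str | None = None
    ecotype_table: str | None = None     # TSV: animal_id, ecotype
    out_dir: str = "migragen_out"

    # telemetry / movement
    min_locations: int = 30              # per season for the overlap index
    max_gap_days: int = 1                # daily-coverage rule for NSD
    isopleth_level: float = 0.95
    rho_min: float = 30.0                # days on the second range
    nsd_ref_days: int = 60               # reference-point search horizon
    nsd_ref_step: int = 10               # candidate subsampling stride
    nsd_n_starts: int = 2

    # genotype QC
    call_rate: float = 0.90
    maf: float = 0.05
    hwe_p: float = 0.001
    max_missingness: float = 0.85
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.5

    # structure
    k_range: tuple = (1, 2, 3)
    cv_folds: int = 5
    em_restarts: int = 2
    em_tol: float = 1e-4
    em_max_iter: int = 500
    fst_bootstrap: int = 1000

    # association
    bonferroni_alpha: float = 0.05
    promoter_bp: int = 2000
    per_snp_lambda: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.isopleth_level < 1.0, "isopleth_level in (0,1)"),
            (0.0 <= self.maf < 0.5, "maf in [0, 0.5)"),
            (0.0 < self.call_rate <= 1.0, "call_rate in (0,1]"),
            (self.rho_min > 0, "rho_min positive"),
            (self.cv_folds >= 2, "cv_folds >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config error: {msg}")

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"config error: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def echo(self):
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(out_dir, stage, config, inputs, outputs):
    man = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs if p and Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "config": config.echo(),
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")
    return path


def _stage_seed(config, stage):
    ss = np.random.SeedSequence(config.seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _write_tsv(df, path, float_format="%.6g"):
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# movement stage

def run_movement_stage(config):
    """Telemetry screening, IO, NSD classification and migration metrics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, projection = tele.read_telemetry(config.telemetry)
    tracks = [tele.assign_seasons(tele.thin_daily(t)) for t in tracks]
    io_elig, io_excl = tele.screen_for_io(tracks, config.min_locations)
    nsd_elig, nsd_excl = tele.screen_for_nsd(tracks, config.max_gap_days)
    by_id = {t.animal_id: t for t in tracks}

    # --- overlap index per eligible animal-season-year
    io_rows = []
    polygons = {}
    for animal_id, season_year in io_elig:
        track = by_id[animal_id]
        df = track.fixes
        parts = {}
        for season in ("summer", "winter"):
            pts = df[(df["season"] == season) & (df["season_year"] == season_year)][
                ["x_km", "y_km"]
            ].to_numpy()
            try:
                ud = mv.estimate_ud(pts)
                parts[season] = mv.isopleth(ud, config.isopleth_level, season=season)
            except ValueError:
                parts[season] = None  # degenerate: all fixes identical
        if parts["summer"] is None or parts["winter"] is None:
            io_value = 1.0  # zero-extent seasonal ranges: fully overlapping
        else:
            io_value = mv.compute_io(parts["summer"], parts["winter"])
            polygons[(animal_id, season_year)] = (parts["summer"], parts["winter"])
        io_rows.append({"animal_id": animal_id, "season_year": season_year,
                        "io": io_value})
    io_df = pd.DataFrame(io_rows, columns=["animal_id", "season_year", "io"])

    # --- NSD classification per eligible animal-year
    fits = {}
    for animal_id, year in nsd_elig:
        track = by_id[animal_id]
        df = track.fixes[track.fixes["timestamp"].dt.year == year]
        sub = tele.TelemetryTrack(animal_id, df.reset_index(drop=True), track.crs)
        try:
            _, res = mv.select_reference_point(
                sub, n_candidate_days=config.nsd_ref_days,
                step=config.nsd_ref_step, min_days=360 - 5 * config.max_gap_days,
                n_starts=config.nsd_n_starts,
            )
        except ValueError as exc:
            logger.warning("%s year %d unclassifiable: %s", animal_id, year, exc)
            continue
        fits.setdefault(animal_id, {})[year] = res.best

    rows = []
    for animal_id in sorted(by_id):
        cls = (mv.classify_animal(animal_id, fits[animal_id])
               if animal_id in fits else None)
        animal_io = io_df[io_df["animal_id"] == animal_id]["io"]
        row = {
            "animal_id": animal_id,
            "io": animal_io.mean() if len(animal_io) else np.nan,
            "nsd_class": cls.final if cls else "no_data",
            "included": bool(cls.included) if cls else False,
            "distance_km": np.nan, "timing_day": np.nan,
            "centroid_distance_km": np.nan, "lat_shift_deg": np.nan,
        }
        if cls and cls.final == "migrant":
            mig_fits = {y: f for y, f in fits[animal_id].items()
                        if f.model in ("migrant", "mixed-migrant")}
            ranges = [polygons[k] for k in polygons if k[0] == animal_id] or None
            start_dates = {
                y: by_id[animal_id]
                .fixes[by_id[animal_id].fixes["timestamp"].dt.year == y]["timestamp"]
                .iloc[0]
                for y in mig_fits
            }
            params = mv.migration_params(animal_id, mig_fits, ranges=ranges,
                                         projection=projection,
                                         start_dates=start_dates)
            row.update(
                distance_km=params.distance_km, timing_day=params.timing_day,
                centroid_distance_km=params.centroid_distance_km,
            )
            if params.lat_shift_deg is not None:
                row["lat_shift_deg"] = params.lat_shift_deg
            elif ranges:
                # already-projected input (km plane): northing shift -> degrees
                shift = np.mean([s.centroid[1] - w.centroid[1] for s, w in ranges])
                row["lat_shift_deg"] = shift / 111.19
        rows.append(row)
    metrics = pd.DataFrame(rows)
    paths = {
        "metrics": out / "movement_metrics.tsv",
        "io_years": out / "io_by_year.tsv",
        "exclusions": out / "screening_exclusions.tsv",
    }
    _write_tsv(metrics, paths["metrics"])
    _write_tsv(io_df, paths["io_years"])
    excl_frames = [
        df for df in
        (io_excl.assign(screen="io").rename(columns={"season_year": "year"}),
         nsd_excl.assign(screen="nsd"))
        if not df.empty
    ]
    excl = (pd.concat(excl_frames, ignore_index=True) if excl_frames
            else pd.DataFrame(columns=["animal_id", "year", "reason", "screen"]))
    _write_tsv(excl, paths["exclusions"])
    _manifest(out, "movement", config, [config.telemetry], list(paths.values()))
    return metrics


# ---------------------------------------------------------------------------
# popgen stage

def run_popgen_stage(config):
    """QC chain, LD/neutral SNP sets, GRM, PCA, admixture + CV, F_ST."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(config, "popgen")
    gm = pg.read_vcf(config.vcf)
    report = pg.FilterReport()
    gm, _ = pg.apply_individual_filters(gm, config.max_missingness, report)
    gm, _ = pg.apply_locus_filters(gm, config.call_rate, config.maf, None, report)
    kept = pg.ld_prune(gm, config.ld_window, config.ld_step, config.ld_r2)
    report.add("ld_prune", f"{config.ld_window}/{config.ld_step}/{config.ld_r2}",
               gm.n_loci, gm.n_loci - len(kept))
    ld_set = gm.take_loci(kept)
    neutral, _ = pg.apply_locus_filters(ld_set, None, None, config.hwe_p, report)

    grm = pg.compute_grm(ld_set)
    evecs, evals = pg.pca(neutral)

    cv, selected_k = pg.cross_validate_k(
        neutral, config.k_range, folds=config.cv_folds, seed=seed,
        n_restarts=1, tol=config.em_tol, max_iter=config.em_max_iter,
    )
    adm = pg.fit_admixture(neutral, selected_k, seed=seed,
                           n_restarts=config.em_restarts, tol=config.em_tol,
                           max_iter=config.em_max_iter)
    labels, max_q, ties = pg.assign_clusters(adm.q)
    fst = None
    if adm.k >= 2 and np.bincount(labels, minlength=adm.k).min() >= 2:
        fst = pg.fst_between(neutral, labels, n_boot=config.fst_bootstrap,
                             seed=seed)

    paths = {}
    qdf = pd.DataFrame(adm.q, columns=[f"q{k + 1}" for k in range(adm.k)])
    qdf.insert(0, "animal_id", neutral.samples)
    qdf["cluster"] = labels + 1
    paths["q"] = out / "admixture_q.tsv"
    _write_tsv(qdf, paths["q"])
    edf = pd.DataFrame(evecs, columns=[f"pc{i + 1}" for i in range(evecs.shape[1])])
    edf.insert(0, "animal_id", neutral.samples)
    paths["pca"] = out / "pca_eigenvectors.tsv"
    _write_tsv(edf, paths["pca"])
    paths["filters"] = out / "filter_report.tsv"
    _write_tsv(report.to_frame(), paths["filters"])
    paths["grm"] = out / "grm.tsv"
    gdf = pd.DataFrame(grm, columns=ld_set.samples)
    gdf.insert(0, "animal_id", ld_set.samples)
    _write_tsv(gdf, paths["grm"])
    paths["ld_set"] = out / "ld_set_loci.tsv"
    _write_tsv(ld_set.loci, paths["ld_set"])
    paths["ld_genotypes"] = out / "ld_set_genotypes.tsv"
    ld_geno = pd.DataFrame(ld_set.g, columns=ld_set.loci["id"])
    ld_geno.insert(0, "animal_id", ld_set.samples)
    _write_tsv(ld_geno, paths["ld_genotypes"])
    summary = {
        "cv_errors": {str(k): v for k, v in cv.items()},
        "selected_k": int(selected_k),
        "loglik": adm.loglik,
        "eigenvalues": [float(v) for v in evals],
        "fst": None if fst is None else {
            "estimate": fst.estimate, "ci_low": fst.ci_low,
            "ci_high": fst.ci_high, "method": fst.method,
        },
        "cluster_sizes": np.bincount(labels, minlength=adm.k).tolist(),
        "mean_q_per_cluster": [
            float(adm.q[labels == k, k].mean()) if (labels == k).any() else None
            for k in range(adm.k)
        ],
    }
    paths["summary"] = out / "popgen_summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _manifest(out, "popgen", config, [config.vcf], list(paths.values()))
    return {"ld_set": ld_set, "neutral": neutral, "grm": grm, "adm": adm,
            "labels": labels, "fst": fst, "cv": cv, "selected_k": selected_k}


# ---------------------------------------------------------------------------
# association stage

PHENOTYPES = ("io", "nsd_class", "distance_km", "timing_day", "lat_shift_deg")


def _phenotype_vector(metrics, kind):
    """Aligned phenotype values with the eligibility mask applied."""
    if kind == "nsd_class":
        ok = metrics["included"] & metrics["nsd_class"].isin(["migrant", "resident"])
        y = (metrics["nsd_class"] == "migrant").astype(float)
    elif kind == "io":
        ok = metrics["io"].notna()
        y = metrics["io"].astype(float)
    else:
        ok = metrics["included"] & metrics[kind].notna() \
            & (metrics["nsd_class"] == "migrant")
        y = metrics[kind].astype(float)
    return y.to_numpy(), ok.to_numpy()


def run_assoc_stage(config, metrics=None, popgen_state=None, min_n=20):
    """Mixed-model association of each SNP with the five phenotypes."""
    out = Path(config.out_dir)
    if metrics is None:
        metrics = pd.read_csv(out / "movement_metrics.tsv", sep="\t")
    if popgen_state is None:
        popgen_state = _reload_popgen_state(out)
    ld_set = popgen_state["ld_set"]
    grm = popgen_state["grm"]
    sample_pos = {s: i for i, s in enumerate(ld_set.samples)}
    metrics = metrics[metrics["animal_id"].isin(sample_pos)].reset_index(drop=True)
    inflation = {}
    paths = []
    all_significant = set()
    genes = pd.read_csv(config.gene_table, sep="\t") if config.gene_table else None
    if genes is None:
        logger.warning("no gene table supplied; SNP annotation skipped")
    for kind in PHENOTYPES:
        y, ok = _phenotype_vector(metrics, kind)
        idx = np.array([sample_pos[a] for a in metrics["animal_id"][ok]])
        if ok.sum() < min_n or np.ptp(y[ok]) == 0:
            logger.warning("phenotype %s: too few eligible individuals (%d), "
                           "skipped", kind, int(ok.sum()))
            continue
        model = assoc.MixedLMM(y[ok], grm[np.ix_(idx, idx)])
        res = model.fit()
        tab = res.test_snps(ld_set.g[idx], per_snp_lambda=config.per_snp_lambda,
                            snp_ids=ld_set.loci["id"].to_numpy())
        m_tests = int((~tab["skipped"]).sum())
        tab["p_bonf"], tab["significant"] = assoc.bonferroni_adjust(
            tab["p_wald"], m_tests, config.bonferroni_alpha
        )
        tab["pve"] = assoc.compute_pve(tab["beta"], tab["se"], tab["maf"],
                                       int(ok.sum()))
        tab["relative_pve_pct"] = np.nan
        sig = tab.index[tab["significant"].fillna(False)]
        if len(sig):
            tab.loc[sig, "relative_pve_pct"] = assoc.relative_pve(
                tab.loc[sig, "pve"].to_numpy()
            )
            all_significant.update(int(j) for j in sig)
        valid = tab.loc[~tab["skipped"], "wald"].dropna()
        if len(valid) >= 100:
            inflation[kind] = assoc.genomic_inflation(valid)
        tab.insert(0, "chrom", ld_set.loci["chrom"].to_numpy())
        tab.insert(1, "pos", ld_set.loci["pos"].to_numpy())
        if genes is not None:
            tab["annotation"] = assoc.annotate_snps(
                ld_set.loci, genes, config.promoter_bp
            ).to_numpy()
        path = out / f"assoc_{kind}.tsv"
        _write_tsv(tab, path)
        paths.append(path)
    infl_path = out / "genomic_inflation.json"
    infl_path.write_text(json.dumps(inflation, indent=2, sort_keys=True) + "\n")
    paths.append(infl_path)

    if all_significant and popgen_state.get("labels") is not None \
            and len(np.unique(popgen_state["labels"])) >= 2:
        labels = popgen_state["labels"]
        snp_idx = sorted(all_significant)
        freq, kw_p, pw = pg.maf_by_cluster(ld_set, labels, snp_idx)
        freq.insert(0, "snp_id", ld_set.loci["id"].iloc[snp_idx].to_numpy())
        maf_path = out / "maf_by_cluster.tsv"
        _write_tsv(freq, maf_path)
        tests_path = out / "maf_cluster_tests.json"
        tests_path.write_text(json.dumps(
            {"kruskal_p": kw_p,
             "pairwise_wilcoxon": {
                 f"{a}|{b}": float(pw.loc[a, b])
                 for i, a in enumerate(pw.index) for b in pw.columns[i + 1:]
             }},
            indent=2) + "\n")
        paths += [maf_path, tests_path]
    _manifest(out, "assoc", config,
              [config.vcf, out / "movement_metrics.tsv"], paths)
    return inflation


def _reload_popgen_state(out):
    """Rebuild the in-memory popgen state from stage outputs on disk."""
    out = Path(out)
    need = [out / "ld_set_genotypes.tsv", out / "grm.tsv", out / "admixture_q.tsv"]
    for p in need:
        if not p.exists():
            raise FileNotFoundError(
                f"missing upstream output {p}; run the 'popgen' subcommand first"
            )
    geno = pd.read_csv(need[0], sep="\t")
    samples = geno["animal_id"].tolist()
    g = geno.drop(columns="animal_id").to_numpy(dtype=float)
    loci_meta = pd.read_csv(out / "ld_set_loci.tsv", sep="\t")
    ld_set = pg.GenotypeMatrix(g, samples, loci_meta)
    grm = pd.read_csv(need[1], sep="\t").drop(columns="animal_id").to_numpy()
    qdf = pd.read_csv(need[2], sep="\t")
    labels = qdf["cluster"].to_numpy() - 1
    q = qdf[[c for c in qdf.columns if c.startswith("q")]].to_numpy()
    return {"ld_set": ld_set, "grm": grm, "labels": labels, "q": q}


# ---------------------------------------------------------------------------
# ancestry stage

def run_ancestry_stage(config, metrics=None, popgen_state=None):
    """Behaviour ~ ancestry regressions and ecotype group comparisons."""
    out = Path(config.out_dir)
    if metrics is None:
        metrics = pd.read_csv(out / "movement_metrics.tsv", sep="\t")
    if popgen_state is None:
        popgen_state = _reload_popgen_state(out)
    q = popgen_state.get("q")
    if q is None:
        q = popgen_state["adm"].q
    samples = popgen_state["ld_set"].samples
    qdf = pd.DataFrame(q, columns=[f"q{k + 1}" for k in range(q.shape[1])])
    qdf["animal_id"] = samples
    merged = metrics.merge(qdf, on="animal_id", how="inner")
    eco = None
    if config.ecotype_table:
        eco_df = pd.read_csv(config.ecotype_table, sep="\t")
        merged = merged.merge(eco_df[["animal_id", "ecotype"]], on="animal_id",
                              how="left")
        eco = merged["ecotype"]

    rows = []
    q_cols = [c for c in merged.columns
              if c.startswith("q") and c[1:].isdigit()]
    io_ok = merged["io"].notna()
    cls_ok = merged["included"] & merged["nsd_class"].isin(["migrant", "resident"])
    status = (merged["nsd_class"] == "migrant").astype(float)
    for qc in q_cols:
        qv = merged[qc].to_numpy()
        if io_ok.sum() >= 3 and np.ptp(qv[io_ok]) > 0:
            rows.append(anc.regress_io_on_q(merged["io"][io_ok], qv[io_ok],
                                            predictor=qc))
            if eco is not None and eco[io_ok].nunique() >= 2:
                rows.append(anc.regress_with_ecotype(
                    merged["io"][io_ok], qv[io_ok], eco[io_ok], "linear",
                    response="IO", predictor=qc))
        if cls_ok.sum() >= 3 and status[cls_ok].nunique() == 2 \
                and np.ptp(qv[cls_ok]) > 0:
            rows.append(anc.regress_migrant_on_q(status[cls_ok], qv[cls_ok],
                                                 predictor=qc))
            if eco is not None and eco[cls_ok].nunique() >= 2:
                rows.append(anc.regress_with_ecotype(
                    status[cls_ok].to_numpy(), qv[cls_ok], eco[cls_ok],
                    "logistic", response="nsd_class", predictor=qc))

    table = pd.DataFrame(
        {
            "model": [
                f"{r.response} ~ {r.predictor}"
                + (" + (1|ecotype)" if r.random_effect_var is not None else "")
                for r in rows
            ],
            "family": [r.family for r in rows],
            "beta": [r.beta for r in rows],
            "std_error": [r.se for r in rows],
            "stat": [r.stat for r in rows],
            "p": [r.p for r in rows],
            "r2": [r.r2 for r in rows],
            "aic": [r.aic for r in rows],
            "n": [r.n for r in rows],
            "random_effect_var": [r.random_effect_var for r in rows],
            "flags": ["; ".join(r.flags) for r in rows],
        }
    )
    paths = {"table": out / "ancestry_regressions.tsv"}
    _write_tsv(table, paths["table"])

    group_tests = {}
    if eco is not None and eco.notna().any():
        for metric in ("io", "distance_km", "timing_day"):
            sel = merged[metric].notna() & eco.notna()
            counts = eco[sel].value_counts()
            sel &= eco.isin(counts[counts >= 2].index)
            if sel.sum() >= 4 and eco[sel].nunique() >= 2:
                kw_p, pw = anc.ecotype_group_tests(merged[metric][sel], eco[sel])
                group_tests[metric] = {
                    "kruskal_p": kw_p,
                    "group_means": merged[sel].groupby(eco[sel])[metric].mean()
                    .round(6).to_dict(),
                    "pairwise_wilcoxon": {
                        f"{a}|{b}": float(pw.loc[a, b])
                        for i, a in enumerate(pw.index)
                        for b in pw.columns[i + 1:]
                    },
                }
    paths["groups"] = out / "ecotype_group_tests.json"
    paths["groups"].write_text(json.dumps(group_tests, indent=2, sort_keys=True)
                               + "\n")
    _manifest(out, "ancestry", config,
              [out / "movement_metrics.tsv", out / "admixture_q.tsv"],
              list(paths.values()))
    return table


def run_pipeline(config):
    """Run all stages in order; returns the ancestry regression table."""
    stage = "movement"
    try:
        metrics = run_movement_stage(config)
        stage = "popgen"
        state = run_popgen_stage(config)
        state["q"] = state["adm"].q
        stage = "assoc"
        run_assoc_stage(config, metrics=metrics, popgen_state=state)
        stage = "ancestry"
        return run_ancestry_stage(config, metrics=metrics, popgen_state=state)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
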