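"""End-to-end pipeline: simulate/load → fit → align → label → dynamics → cycles
→ assays → associations, with TSV artifacts and a plain-text report.

All randomness funnels through one seed, expanded deterministically per stage;
identical config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import align_topics, select_k, topic_diagnostics
from .assays import test_cyclicity_batch
from .associations import (build_design, fit_dirichlet_regression,
                           participant_topic_means, test_preterm)
from .cycles import (HsmmParams, cycle_change_magnitude, identify_cycles,
                     rv_permutation_test, screen_diary, standardize_cycledays,
                     align_cycles)
from .data_model import CompositionMatrix, DataError, load_counts, load_sample_table, to_relative
from .dynamics import (classify_stability_by_participant, compare_dominance_sources,
                       evaluate_dominance, make_transition_pairs, predict_from_subcst,
                       predict_from_topics, representation_error)
from .lda import fit_lda_range
from .reference import ReferenceCentroids, assign_subcst, harmonize_taxa, label_topics_fit
from .synthetic import (GeneratorConfig, LACTOBACILLUS_TAXA, default_centroids,
                        simulate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the analysis conventions.

    With ``counts_path`` unset the synthetic generator provides the cohort.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    centroids_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    K_values: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    lda_iterations: int = 600
    lda_burn_in: int = 200
    stability_threshold: float = 0.25
    stability_thresholds_sensitivity: tuple[float, float] = (0.15, 0.35)
    stability_window: int = 5
    minority_weight: float = 10.0
    n_repeats: int = 10
    train_fraction: float = 0.8
    n_perm: int = 199
    spline_df: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=gen, **raw)


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the artifacts directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                                     if k != "generator"},
                      "stages": []}

    # --- data -----------------------------------------------------------
    if config.counts_path:
        cm = load_counts(config.counts_path)
        meta = load_sample_table(config.metadata_path)
        cohort = None
    else:
        gen = dataclasses.replace(config.generator, seed=_stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(gen)
        cm, meta = cohort.counts, cohort.meta
    cm.to_frame().to_csv(outdir / "counts.tsv", sep="\t")
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    manifest["stages"].append("data")

    centroids = (ReferenceCentroids.from_csv(config.centroids_path)
                 if config.centroids_path else default_centroids())

    # --- topics ---------------------------------------------------------
    fits = fit_lda_range(cm, config.K_values, seed=_stage_seed(config.seed, "lda"),
                         n_iterations=config.lda_iterations, burn_in=config.lda_burn_in)
    if len(fits) >= 2:
        graph = topic_diagnostics(align_topics(fits))
        K_star = select_k(graph)
        scores = pd.DataFrame(
            [{"K": graph.K_values[n.model], "topic": n.topic, "path": n.path,
              "mass": n.mass, "coherence": n.coherence, "refinement": n.refinement}
             for n in graph.nodes])
        scores.to_csv(outdir / "alignment_scores.tsv", sep="\t", index=False)
        with open(outdir / "alignment_graph.json", "w") as fh:
            json.dump(graph.to_dict(), fh, indent=1)
    else:
        logger.info("single K requested: alignment stage skipped")
        K_star = fits[0].K
    fit = fits[config.K_values.index(K_star)]
    fit.save(outdir / "lda_fit")
    manifest["K_selected"] = int(K_star)
    manifest["stages"] += ["topics", "alignment"]

    # --- labelling and composition prediction ---------------------------
    labels, dissim = label_topics_fit(fit, centroids)
    dissim.to_csv(outdir / "topic_centroid_dissimilarity.tsv", sep="\t")
    pd.Series(labels, name="label").rename_axis("topic").to_csv(
        outdir / "topic_labels.tsv", sep="\t")

    rel = to_relative(cm)
    rel_h = harmonize_taxa(rel, centroids)
    sample_labels = assign_subcst(rel, centroids)
    pd.DataFrame({"sample": cm.sample_ids, "subcst": sample_labels}).to_csv(
        outdir / "sample_subcst.tsv", sep="\t", index=False)
    pred_t = harmonize_taxa(predict_from_topics(fit), centroids)
    pred_s = predict_from_subcst(sample_labels, centroids, sample_ids=cm.sample_ids)
    pred_s = harmonize_taxa(pred_s, centroids)
    # align taxa across the three matrices
    taxa = sorted(set(rel_h.taxon_ids) | set(pred_t.taxon_ids) | set(pred_s.taxon_ids))

    def expand(c: CompositionMatrix) -> CompositionMatrix:
        v = np.zeros((c.n_rows, len(taxa)))
        for j, t in enumerate(c.taxon_ids):
            v[:, taxa.index(t)] = c.values[:, j]
        return CompositionMatrix(list(c.row_ids), list(taxa), v)

    rep = representation_error(expand(rel_h), expand(pred_t), expand(pred_s))
    pd.DataFrame({"sample": cm.sample_ids, "bc_topics": rep.bc_topics,
                  "bc_subcst": rep.bc_subcst}).to_csv(
        outdir / "representation_error.tsv", sep="\t", index=False)
    manifest["representation"] = {"mean_difference": rep.mean_difference,
                                  "p_value": rep.p_value}
    manifest["stages"] += ["labels", "prediction"]

    # --- stability and dominance ----------------------------------------
    participants = meta.loc[cm.sample_ids, "participant"].tolist()
    stability = {}
    for thr in (config.stability_threshold, *config.stability_thresholds_sensitivity):
        stability[thr] = classify_stability_by_participant(
            rel, participants, threshold=thr, window=config.stability_window)
    stab_df = pd.DataFrame({"sample": cm.sample_ids,
                            **{f"stable_{t}": v for t, v in stability.items()}})
    stab_df.to_csv(outdir / "stability.tsv", sep="\t", index=False)

    lacto = set(LACTOBACILLUS_TAXA) & set(cm.taxon_ids)
    dom_summary = None
    if lacto:
        pairs = make_transition_pairs(rel, participants, fit.gamma, lacto,
                                      subcst_labels=sample_labels)
        dominant = [p for p in pairs if p.current_dominant]
        if dominant and len({p.outcome_loss for p in dominant}) == 2:
            results = evaluate_dominance(
                pairs, n_repeats=config.n_repeats, train_fraction=config.train_fraction,
                minority_weight=config.minority_weight,
                seed=_stage_seed(config.seed, "dominance"))
            results.to_csv(outdir / "dominance_metrics.tsv", sep="\t", index=False)
            if results["valid"].any():
                dom_summary = compare_dominance_sources(results)
            switch_rate = float(np.mean([p.outcome_loss for p in dominant]))
            manifest["dominance"] = {"switch_rate": switch_rate, **(dom_summary or {})}
        else:
            logger.info("dominance stage skipped: single outcome class")
    manifest["stages"] += ["stability", "dominance"]

    # --- cycles ----------------------------------------------------------
    np_meta = meta[meta["cohort"] == "NP-UAB"]
    cycle_rows, rv_rows = [], []
    hsmm = HsmmParams()
    for pid, sub in np_meta.groupby("participant"):
        sub = sub.sort_values("day")
        diary = sub["bleeding"].to_numpy(dtype=int)
        included, reason = screen_diary(diary, study_days=len(diary))
        if not included:
            cycle_rows.append({"participant": pid, "status": f"excluded ({reason})"})
            continue
        onsets = identify_cycles(diary, hsmm)
        if not onsets:
            cycle_rows.append({"participant": pid, "status": "no cycle identified"})
            continue
        ct = standardize_cycledays(onsets, sub["day"].tolist())
        cycle_rows.append({"participant": pid, "status": "ok",
                           "n_onsets": len(onsets),
                           "onsets": ";".join(map(str, onsets))})
        tab = ct.table.assign(sample=sub.index.to_numpy())
        ok = tab.dropna(subset=["cycleday"])
        if ok["cycle_index"].nunique() >= 2:
            g = fit.gamma[[cm.sample_ids.index(s) for s in ok["sample"]]]
            cyc = ok["cycle_index"].to_numpy()
            first, second = np.unique(cyc)[:2]
            try:
                Xa, Xb = align_cycles(
                    ok.loc[cyc == first, "cycleday"].to_numpy(float), g[cyc == first],
                    ok.loc[cyc == second, "cycleday"].to_numpy(float), g[cyc == second])
                rv, p = rv_permutation_test(Xa, Xb, n_perm=config.n_perm,
                                            seed=_stage_seed(config.seed, f"rv:{pid}"))
                mag = cycle_change_magnitude(ok["cycleday"].to_numpy(float), g)
                rv_rows.append({"participant": pid, "rv": rv, "p": p,
                                "change_magnitude": mag})
            except DataError as e:
                rv_rows.append({"participant": pid, "rv": np.nan, "p": np.nan,
                                "note": str(e)})
    pd.DataFrame(cycle_rows).to_csv(outdir / "cycles.tsv", sep="\t", index=False)
    if rv_rows:
        rv_df = pd.DataFrame(rv_rows)
        if rv_df["p"].notna().any():
            from .assays import bh_adjust
            valid = rv_df["p"].notna()
            rv_df.loc[valid, "p_adj"] = bh_adjust(rv_df.loc[valid, "p"].to_numpy())
        rv_df.to_csv(outdir / "cycle_agreement.tsv", sep="\t", index=False)
    manifest["stages"].append("cycles")

    # --- cyclicity of topics ---------------------------------------------
    cyc_res = None
    cycledays_by_sample: dict[str, int] = {}
    for row in cycle_rows:
        if row.get("status") == "ok":
            pid = row["participant"]
            sub = np_meta[np_meta["participant"] == pid].sort_values("day")
            onsets = [int(x) for x in row["onsets"].split(";")]
            ct = standardize_cycledays(onsets, sub["day"].tolist())
            for s, cd in zip(sub.index, ct.table["cycleday"]):
                if pd.notna(cd):
                    cycledays_by_sample[s] = int(cd)
    if len(cycledays_by_sample) >= 30:
        samples = list(cycledays_by_sample)
        cds = np.array([cycledays_by_sample[s] for s in samples])
        idx = [cm.sample_ids.index(s) for s in samples]
        from .assays import AssayMatrix
        topic_assay = AssayMatrix(samples, list(fit.topic_ids),
                                  fit.gamma[idx], transform="raw")
        if len(np.unique(cds)) >= 8:
            cyc_res = test_cyclicity_batch(topic_assay, cds, kind="proportion",
                                           df=config.spline_df)
            cyc_res.to_csv(outdir / "topic_cyclicity.tsv", sep="\t", index=False)
    manifest["stages"].append("cyclicity")

    # --- host associations -----------------------------------------------
    means = participant_topic_means(fit.gamma, participants, list(fit.topic_ids))
    means.to_csv(outdir / "participant_topic_means.tsv", sep="\t")
    X = build_design(meta.reset_index())
    X = X.loc[means.index]
    drop = [c for c in X.columns if c != "intercept" and X[c].nunique() < 2]
    dirich = fit_dirichlet_regression(means, X.drop(columns=drop))
    dirich.summary().to_csv(outdir / "dirichlet_regression.tsv", sep="\t", index=False)
    manifest["dirichlet_converged"] = dirich.converged

    preterm = meta.groupby("participant")["preterm"].first()
    preg = meta.groupby("participant")["pregnant"].first()
    preterm = preterm[preg.astype(bool)].dropna()
    try:
        pt = test_preterm(means.loc[means.index.intersection(preterm.index)],
                          preterm.astype(bool))
        pt.to_csv(outdir / "preterm_association.tsv", sep="\t", index=False)
    except DataError as e:
        logger.info("preterm stage skipped: %s", e)
    manifest["stages"].append("associations")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return outdir


def write_report(artifacts: str | Path) -> Path:
    """Single human-readable summary of a completed run, cross-checked from the TSVs."""
    artifacts = Path(artifacts)
    with open(artifacts / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [
        "vmtopics pipeline report",
        "========================",
        f"seed: {manifest['seed']}",
        f"selected number of topics K*: {manifest.get('K_selected', 'not run')}",
        "",
    ]
    labels_path = artifacts / "topic_labels.tsv"
    if labels_path.exists():
        labs = pd.read_csv(labels_path, sep="\t")
        lines.append("topic labels: " + ", ".join(
            f"{r.topic}→{r.label}" for r in labs.itertuples()))
    rep = manifest.get("representation")
    if rep:
        lines.append(
            f"representation error (mean BC difference, sub-CST − topics): "
            f"{rep['mean_difference']:.4f} (one-sided paired t-test p = {rep['p_value']:.3g})")
    dom = manifest.get("dominance")
    if dom:
        lines.append(
            f"dominance loss: switch rate {dom['switch_rate']:.3f}; "
            f"median F1 topics {dom.get('median_f1_topics', float('nan')):.3f} vs "
            f"sub-CST {dom.get('median_f1_subcst', float('nan')):.3f} "
            f"(Wilcoxon p = {dom.get('p_value', float('nan')):.3g})")
    else:
        lines.append("dominance loss: not run")
    rv_path = artifacts / "cycle_agreement.tsv"
    if rv_path.exists():
        rv = pd.read_csv(rv_path, sep="\t")
        sig = int((rv.get("p_adj", rv["p"]) < 0.05).sum())
        lines.append(f"cycle agreement: {sig}/{len(rv)} participants with "
                     f"significant between-cycle RV (adj. p < 0.05)")
    else:
        lines.append("cycle agreement: not run")
    cyc_path = artifacts / "topic_cyclicity.tsv"
    if cyc_path.exists():
        cyc = pd.read_csv(cyc_path, sep="\t")
        lines.append(f"cyclic topics: {int(cyc['significant'].sum())}/{len(cyc)} "
                     f"at adjusted p < 0.05")
    else:
        lines.append("topic cyclicity: not run")
    report = artifacts / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report


def checksum_artifacts(artifacts: str | Path) -> dict[str, str]:
    """SHA-256 of every artifact file (for determinism checks)."""
    artifacts = Path(artifacts)
    out = {}
    for f in sorted(artifacts.rglob("*")):
        if f.is_file():
            out[str(f.relative_to(artifacts))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out
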