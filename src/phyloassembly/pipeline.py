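"""End-to-end orchestration: filter -> turnover -> Raup-Crick ->
classification -> phyloscores -> phylofactorization -> ecology ->
chronosequence, with deterministic seeding and TSV/JSON outputs."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from . import ecology, phylofactor, phyloscore, raupcrick, turnover
from .classify import Thresholds, classify_pairs, pairs_needing_rc, summarize_group
from .io import AlignedBundle

logger = logging.getLogger(__name__)


def substream(master_seed: int, *labels) -> np.random.SeedSequence:
    """Named, collision-resistant child seed stream.

    Every stage/group derives its randomness from the master seed plus a
    stable hash of its labels, so stage-level reruns reproduce pipeline
    runs exactly and no two stages share a stream.
    """
    key = tuple(zlib.crc32(str(l).encode()) for l in labels)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; echoed verbatim into the manifest."""

    output_dir: str = "results"
    tree_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    counts_orientation: str = "asv_rows"
    group_cols: tuple = ("floodplain", "stream_type")
    region_col: str = "region"
    n_reps_bnti: int = 999
    n_reps_rc: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    conspecifics: str = "include"
    force_rc_all_pairs: bool = False
    alpha: float = 0.001
    min_clade: int = 2
    report_min_clade: int = 20
    agreement: float = 0.8
    top_n_genera: int = 30
    environment_vars: tuple = ("chlorophyll_a", "bacterial_abundance")
    seed: int = 0

    def __post_init__(self):
        if not (self.bnti_threshold > 0 and 0 < self.rc_threshold <= 1):
            raise ValueError("thresholds out of range")
        if not 0 < self.alpha < 1 or not 0 < self.agreement <= 1:
            raise ValueError("alpha/agreement out of range")


def load_bundle(config: RunConfig) -> AlignedBundle:
    tree = pio.read_tree(config.tree_path)
    counts = pio.read_counts(config.counts_path, config.counts_orientation)
    tax = pio.read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    meta = pio.read_metadata(config.metadata_path) if config.metadata_path else None
    return pio.align_inputs(tree, counts, tax, meta)


def _group_key(values) -> str:
    return "_".join(str(v) for v in values)


def analyze_group(
    key: str,
    rel: pd.DataFrame,
    counts: pd.DataFrame,
    d: np.ndarray,
    taxon_ids: list[str],
    tree,
    config: RunConfig,
) -> dict:
    """Run turnover, RC, classification and phyloscore stages for one
    group of samples, sharing one tip-permutation stream per group."""
    thresholds = Thresholds(config.bnti_threshold, config.rc_threshold)
    perms = turnover.tip_permutations(
        len(taxon_ids), config.n_reps_bnti, substream(config.seed, "null", key)
    )
    bnti = turnover.group_beta_nti(
        rel, d, taxon_ids, permutations=perms, conspecifics=config.conspecifics
    )
    if config.force_rc_all_pairs:
        pairs = None
    else:
        pairs = pairs_needing_rc(bnti, thresholds)
    rc = raupcrick.group_rc_bray(
        counts,
        n_reps=config.n_reps_rc,
        seed=substream(config.seed, "rc", key),
        pairs=pairs,
    ) if (pairs is None or pairs) else pd.DataFrame(
        columns=["sample_a", "sample_b", "bray_curtis_obs", "rc_bray", "n_reps"]
    )
    classified = classify_pairs(bnti, rc, thresholds)
    summary = summarize_group(classified, key)
    scores = phyloscore.asv_phyloscores(
        rel, d, taxon_ids, permutations=perms, keep_pair_scores=False
    )
    factors = phylofactor.phylofactorize(
        tree,
        scores.totals[scores.n_pairs_scored > 0],
        alpha=config.alpha,
        min_clade=config.min_clade,
    )
    return {
        "bnti": bnti,
        "rc": rc,
        "classified": classified,
        "summary": summary,
        "phyloscores": scores,
        "factors": factors,
        "hos": phylofactor.hos_filter(factors),
    }


def run_pipeline(config: RunConfig, bundle: AlignedBundle | None = None) -> Path:
    """Execute all stages and write TSV outputs plus a JSON manifest.

    Reruns with the same config and inputs reproduce bit-identical
    numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    stage = "load"
    try:
        if bundle is None:
            bundle = load_bundle(config)
        meta = bundle.metadata
        if meta is None:
            raise ValueError("metadata required for the grouped pipeline")

        stage = "filter"
        counts = pio.filter_asvs(
            bundle.counts, meta[config.group_cols[0]], bundle.taxonomy
        )
        aligned = pio.align_inputs(bundle.tree, counts, bundle.taxonomy, meta)
        counts, tree, tax = aligned.counts, aligned.tree, aligned.taxonomy
        rel = counts.relative()

        stage = "cophenetic"
        taxon_ids, d = turnover.cophenetic_distances(tree)
        rel = rel.reindex(columns=taxon_ids)
        cdf = counts.counts.reindex(columns=taxon_ids)

        stage = "groups"
        groups = meta.loc[counts.samples].groupby(list(config.group_cols), observed=True)
        results, hos_sets = {}, {}
        for gvals, gmeta in groups:
            key = _group_key(gvals if isinstance(gvals, tuple) else (gvals,))
            samples = [s for s in gmeta.index if rel.loc[s].sum() > 0]
            if len(samples) < 2:
                logger.warning("group %s skipped (<2 non-empty samples)", key)
                continue
            res = analyze_group(
                key, rel.loc[samples], cdf.loc[samples], d, taxon_ids, tree, config
            )
            results[key] = res
            hos_sets[gvals] = set().union(
                *(f.asv_members for f in res["hos"])
            ) if res["hos"] else set()

        stage = "write_group_tables"
        for name, col in (
            ("bnti", "bnti"), ("rc", "rc"), ("classified", "classified"),
        ):
            frames = [
                res[col].assign(group=key) for key, res in results.items()
                if not res[col].empty
            ]
            table = pd.concat(frames) if frames else pd.DataFrame()
            pio.write_tsv(table, out / f"{name}.tsv")
        pio.write_tsv(
            pd.concat([res["summary"] for res in results.values()])
            if results else pd.DataFrame(),
            out / "process_summary.tsv",
        )
        clade_frames, member_frames, totals_frames = [], [], []
        for key, res in results.items():
            factors = res["factors"]
            if tax is not None:
                phylofactor.annotate_clades(factors, tax, config.agreement)
            all_t = phylofactor.clades_table(factors).assign(group=key)
            clade_frames.append(all_t)
            member_frames.append(
                phylofactor.membership_table(res["hos"]).assign(group=key)
            )
            totals_frames.append(
                res["phyloscores"].totals.rename("total_phyloscore")
                .to_frame()
                .assign(
                    n_pairs_scored=res["phyloscores"].n_pairs_scored, group=key
                )
                .reset_index()
            )
        clade_frames = [f for f in clade_frames if not f.empty]
        pio.write_tsv(
            pd.concat(clade_frames) if clade_frames else pd.DataFrame(),
            out / "clades_all.tsv",
        )
        if clade_frames:
            allc = pd.concat(clade_frames)
            pio.write_tsv(
                allc[(allc.direction == "lower")
                     & (allc.n_asvs > config.report_min_clade)],
                out / "clades_hos_report.tsv",
            )
        member_frames = [f for f in member_frames if not f.empty]
        pio.write_tsv(
            pd.concat(member_frames) if member_frames else pd.DataFrame(),
            out / "hos_membership.tsv",
        )
        pio.write_tsv(
            pd.concat([f for f in totals_frames if not f.empty]) if any(not f.empty for f in totals_frames) else pd.DataFrame(),
            out / "total_phyloscores.tsv",
        )

        stage = "categories"
        fp_col, stream_col = config.group_cols[0], config.group_cols[1]
        cat_frames = []
        floodplains = meta.loc[counts.samples, fp_col].dropna().unique()
        streams = sorted(meta.loc[counts.samples, stream_col].dropna().unique())
        for fp in floodplains:
            if len(streams) != 2:
                break
            s1 = hos_sets.get((fp, streams[0]), set())
            s2 = hos_sets.get((fp, streams[1]), set())
            fp_samples = meta.index[meta[fp_col] == fp].intersection(counts.samples)
            observed = set(
                counts.counts.loc[fp_samples].columns[
                    counts.counts.loc[fp_samples].sum(axis=0) > 0
                ]
            )
            cats = phylofactor.presence_categories(
                s1, s2, observed, labels=(streams[0], streams[1])
            ).assign(floodplain=fp)
            cat_frames.append(cats)
        pio.write_tsv(
            pd.concat([f for f in cat_frames if not f.empty]) if any(not f.empty for f in cat_frames) else pd.DataFrame(),
            out / "presence_categories.tsv",
        )

        stage = "ecology"
        contrib_frames = []
        for (fp, st), hos in hos_sets.items():
            gsamples = meta.index[
                (meta[fp_col] == fp) & (meta[stream_col] == st)
            ].intersection(counts.samples)
            contrib = ecology.hos_contribution(rel.loc[gsamples], hos)
            contrib[fp_col] = fp
            contrib[stream_col] = st
            contrib_frames.append(contrib)
        contributions = (
            pd.concat([f for f in contrib_frames if not f.empty])
            if any(not f.empty for f in contrib_frames)
            else pd.DataFrame()
        )
        pio.write_tsv(contributions.reset_index(), out / "hos_contributions.tsv")
        eco_summary = {}
        if not contributions.empty and len(streams) == 2:
            for metric in ("richness_fraction", "abundance_fraction"):
                try:
                    eco_summary[metric] = ecology.group_comparison(
                        contributions[metric], meta[stream_col]
                    )
                except ValueError as exc:
                    logger.warning("group comparison skipped: %s", exc)
        if "chlorophyll_a" in meta.columns and not contributions.empty:
            models = ecology.chla_models(
                contributions[["richness_fraction", "abundance_fraction"]],
                meta["chlorophyll_a"],
                meta[fp_col],
            )
            pio.write_tsv(models, out / "chla_models.tsv")
            corr_frames = []
            if tax is not None:
                for fp in floodplains:
                    hos_fp = set().union(
                        *(hos_sets.get((fp, st), set()) for st in streams)
                    )
                    fp_samples = meta.index[meta[fp_col] == fp].intersection(
                        counts.samples
                    )
                    corr, matrix = ecology.genus_heatmap_stats(
                        rel.loc[fp_samples], tax, hos_fp,
                        meta.loc[fp_samples, "chlorophyll_a"],
                        top_n=config.top_n_genera,
                    )
                    corr_frames.append(corr.assign(floodplain=fp))
                    if not matrix.empty:
                        matrix.to_csv(
                            out / f"genus_heatmap_{fp}.tsv", sep="\t"
                        )
            pio.write_tsv(
                pd.concat([f for f in corr_frames if not f.empty]) if any(not f.empty for f in corr_frames) else pd.DataFrame(),
                out / "genus_chla_correlations.tsv",
            )

        stage = "chronosequence"
        chrono_frames, env_frames = [], []
        if config.region_col in meta.columns:
            rgroups = meta.loc[counts.samples].groupby(
                list(config.group_cols) + [config.region_col], observed=True
            )
            for gvals, gmeta in rgroups:
                key = _group_key(gvals)
                samples = [s for s in gmeta.index if rel.loc[s].sum() > 0]
                if len(samples) < 2:
                    logger.warning(
                        "chronosequence subgroup %s skipped (n=%d)",
                        key, len(samples),
                    )
                    continue
                res = analyze_group(
                    key, rel.loc[samples], cdf.loc[samples], d, taxon_ids,
                    tree, config,
                )
                chrono_frames.append(res["summary"])
            for fp in floodplains:
                sub = meta.loc[meta[fp_col] == fp]
                if sub[config.region_col].nunique() == 2:
                    env = ecology.compare_environment(
                        sub, [v for v in config.environment_vars if v in sub.columns],
                        config.region_col,
                    )
                    env_frames.append(env.assign(floodplain=fp))
        pio.write_tsv(
            pd.concat([f for f in chrono_frames if not f.empty]) if any(not f.empty for f in chrono_frames) else pd.DataFrame(),
            out / "chronosequence_summary.tsv",
        )
        pio.write_tsv(
            pd.concat([f for f in env_frames if not f.empty]) if any(not f.empty for f in env_frames) else pd.DataFrame(),
            out / "environment_up_dn.tsv",
        )

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "n_samples": int(len(counts.samples)),
            "n_asvs": int(len(counts.asvs)),
            "groups": {
                key: {
                    "n_pairs": int(len(res["classified"])),
                    "n_factors": len(res["factors"]),
                    "n_hos_clades": len(res["hos"]),
                }
                for key, res in results.items()
            },
            "ecology": eco_summary,
            "dropped": {k: len(v) for k, v in aligned.dropped.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        (out / "FAILED").write_text(f"pipeline failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return out
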