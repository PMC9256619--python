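"""End-to-end orchestration: synthetic data (or TSV inputs) -> rarefaction
-> window splitting -> stability statistics -> all-correlation analysis ->
co-occurrence networks -> null checks, with every stage's artifacts written
under one run directory together with a manifest.

Identical config and seed give byte-identical numeric outputs.
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

from . import correlations, io_prep, networks, nulls, stability, synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``inputs`` points at TSV files (counts_16s, counts_its,
    taxonomy, metadata) or ``synth`` parameterizes the generator
    (n_bacteria, n_fungi, effects: "default"|"null", compartments).
    """

    outdir: str = "run"
    seed: int = 0
    synth: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    depth: int = 10_000
    min_occurrence: int = 8
    rho_min: float = 0.6
    q_max: float = 0.05
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    n_perm: int = 999
    null_iters: int = 20
    spatial_check: bool = True

    def __post_init__(self):
        if not (0 <= self.rho_min <= 1 and 0 <= self.q_max <= 1):
            raise ValueError("thresholds out of range")
        if self.depth < 1 or self.min_occurrence < 1 or self.n_perm < 1:
            raise ValueError("depth, min_occurrence and n_perm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _load_data(config: RunConfig) -> synth.SynthDataset:
    if config.inputs:
        try:
            bact = io_prep.read_count_table(config.inputs["counts_16s"])
            fung = io_prep.read_count_table(config.inputs["counts_its"])
            tax = io_prep.read_taxonomy(config.inputs["taxonomy"])
            meta = io_prep.read_metadata(config.inputs["metadata"])
        except KeyError as e:
            raise ValueError(f"[input] missing input path: {e}") from e
        return synth.SynthDataset(bact, fung, tax, meta, {"inputs": dict(config.inputs)})
    opts = dict(config.synth)
    effects_name = opts.pop("effects", "default")
    effects = synth.EffectSpec.null() if effects_name == "null" else synth.EffectSpec()
    compartments = tuple(opts.pop("compartments", synth.COMPARTMENTS))
    design = synth.DesignSpec(compartments=compartments)
    return synth.generate_counts(
        design,
        effects,
        n_bacteria=int(opts.pop("n_bacteria", 200)),
        n_fungi=int(opts.pop("n_fungi", 100)),
        seed=config.seed,
    )


def _stability_stage(data, outdir: Path) -> pd.DataFrame:
    """Resistance/resilience per compartment x kingdom x resolution, plus
    kingdom contrasts on shared plot pairs."""
    rows, contrasts = [], []
    compartments = sorted(data.metadata["compartment"].unique())
    tables = {"bacteria": data.bacteria, "fungi": data.fungi}
    family_tax = data.taxonomy.loc[data.taxonomy["kingdom"] == "fungi"]
    excess: dict = {}
    resil: dict = {}
    for comp in compartments:
        meta_c = data.metadata.loc[data.metadata["compartment"] == comp]
        for kingdom, table in tables.items():
            resolutions = {"otu": table}
            if kingdom == "fungi":
                resolutions["family"] = io_prep.aggregate_family(table, family_tax)
            for res, tab in resolutions.items():
                sub = tab.loc[tab.index.intersection(meta_c.index)]
                if kingdom == "fungi" and comp == "leaf":
                    sub = sub.loc[meta_c.loc[sub.index, "week"] > 8]
                if sub.shape[0] < 4:
                    logger.warning("[stability] skipping %s/%s/%s: too few samples",
                                   comp, kingdom, res)
                    continue
                D = stability.bray_curtis(sub)
                meta_s = meta_c.loc[sub.index]
                weeks_avail = set(meta_s["week"])
                d_weeks = tuple(w for w in io_prep.DROUGHT_WEEKS if w in weeks_avail)
                if d_weeks:
                    resist = stability.resistance_table(D, meta_s, d_weeks)
                    resist["phase"] = "drought"
                    if res == "otu":
                        for w in d_weeks:
                            excess[(comp, kingdom, w)] = stability.between_pair_excess(
                                D, meta_s, w
                            )
                else:
                    resist = pd.DataFrame()
                r_weeks = tuple(w for w in range(9, 18) if w in weeks_avail)
                if 8 in weeks_avail and r_weeks:
                    resi = stability.resilience_series(D, meta_s, 8, r_weeks)
                    resi["phase"] = "rewetting"
                    if res == "otu":
                        for w in r_weeks:
                            resil[(comp, kingdom, w)] = stability.resilience_pairs(
                                D, meta_s, 8, w
                            )
                else:
                    resi = pd.DataFrame()
                for df in (resist, resi):
                    if not df.empty:
                        df["compartment"], df["kingdom"], df["resolution"] = comp, kingdom, res
                        rows.append(df)
        # kingdom contrasts on the OTU-level per-pair statistics: per week,
        # plus window-pooled rows (per-week directions are noisy; pooling
        # the window is the power-appropriate readout of the asymmetry)
        for (mode, store) in (("resistance", excess), ("resilience", resil)):
            weeks = sorted({w for (c, k, w) in store if c == comp})
            pooled_b, pooled_f = {}, {}
            for w in weeks:
                kb, kf = store.get((comp, "bacteria", w)), store.get((comp, "fungi", w))
                if kb is None or kf is None:
                    continue
                if mode == "resistance" or w >= 15:  # late-rewetting pool
                    pooled_b.update({f"w{w}|{k}": v for k, v in kb.items()})
                    pooled_f.update({f"w{w}|{k}": v for k, v in kf.items()})
                try:
                    c = stability.kingdom_contrast(kb, kf, mode=mode)
                except ValueError:
                    continue
                c.update({"compartment": comp, "week": w})
                contrasts.append(c)
            if pooled_b and pooled_f:
                c = stability.kingdom_contrast(
                    pd.Series(pooled_b), pd.Series(pooled_f), mode=mode
                )
                c.update({"compartment": comp, "week": "pooled"})
                contrasts.append(c)
    result = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    contrast_df = pd.DataFrame(contrasts)
    # dual-resolution robustness for fungi
    robust_frames = []
    if not result.empty:
        for comp in compartments:
            for phase in ("drought", "rewetting"):
                sel = result[
                    (result["compartment"] == comp)
                    & (result["kingdom"] == "fungi")
                    & (result["phase"] == phase)
                ]
                otu = sel[sel["resolution"] == "otu"]
                fam = sel[sel["resolution"] == "family"]
                if otu.empty or fam.empty:
                    continue
                rb = stability.dual_resolution_consistency(otu, fam)
                rb["compartment"], rb["phase"] = comp, phase
                robust_frames.append(rb)
    result.to_csv(outdir / "stability.tsv", sep="\t", index=False)
    contrast_df.to_csv(outdir / "stability_kingdom_contrasts.tsv", sep="\t", index=False)
    if robust_frames:
        pd.concat(robust_frames, ignore_index=True).to_csv(
            outdir / "stability_fungi_robust.tsv", sep="\t", index=False
        )
    return result


def _correlation_datasets(data, config: RunConfig):
    """Per (window, treatment, compartment): occurrence-filtered combined
    two-kingdom table on the samples shared by the 16S and ITS tables."""
    out = {}
    for comp in sorted(data.metadata["compartment"].unique()):
        meta_c = data.metadata.loc[data.metadata["compartment"] == comp]
        b_windows = io_prep.split_windows(
            data.bacteria.loc[data.bacteria.index.intersection(meta_c.index)],
            data.metadata, kingdom="bacteria",
        )
        f_windows = io_prep.split_windows(
            data.fungi.loc[data.fungi.index.intersection(meta_c.index)],
            data.metadata, kingdom="fungi",
        )
        for window in ("drought", "rewetting"):
            bt, bm = b_windows[window]
            ft, _ = f_windows[window]
            shared = bt.index.intersection(ft.index)
            for treatment in ("control", "drought"):
                samples = shared[bm.loc[shared, "treatment"] == treatment]
                if len(samples) >= 4:
                    combined = pd.concat([bt.loc[samples], ft.loc[samples]], axis=1)
                else:
                    # fungal samples excluded (early leaves): bacteria-only
                    samples = bt.index[bm["treatment"] == treatment]
                    if len(samples) < 4:
                        continue
                    combined = bt.loc[samples]
                out[(window, treatment, comp)] = io_prep.filter_occurrence(
                    combined, config.min_occurrence
                )
    return out


def run_pipeline(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        data = _load_data(config)
        if data.taxonomy is None or data.taxonomy.empty:
            raise ValueError("taxonomy table is empty")

        stage = "prep"
        rng_seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
        data.bacteria = io_prep.rarefy(data.bacteria, config.depth, int(rng_seeds[0]))
        data.fungi = io_prep.rarefy(data.fungi, config.depth, int(rng_seeds[1]))
        shared = data.bacteria.index.intersection(data.fungi.index)
        data.bacteria, data.fungi = data.bacteria.loc[shared], data.fungi.loc[shared]
        data.metadata = data.metadata.loc[shared]

        stage = "stability"
        _stability_stage(data, outdir)

        stage = "correlations"
        kingdoms = data.taxonomy["kingdom"]
        datasets = _correlation_datasets(data, config)
        all_records = {}
        summaries = []
        for (window, treatment, comp), table in datasets.items():
            recs = correlations.spearman_records(table)
            recs = correlations.partition_link_classes(recs, kingdoms)
            all_records[(window, treatment, comp)] = recs
            for cls, grp in recs.groupby("link_class"):
                s = correlations.summarize(grp)
                s.update(window=window, treatment=treatment, compartment=comp,
                         link_class=cls)
                summaries.append(s)
            recs.to_csv(
                outdir / f"correlations_{window}_{treatment}_{comp}.tsv",
                sep="\t", index=False,
            )
        pd.DataFrame(summaries).to_csv(
            outdir / "correlation_summaries.tsv", sep="\t", index=False
        )
        sgh_frames = []
        for window in ("drought", "rewetting"):
            strata = {}
            for comp in sorted(data.metadata["compartment"].unique()):
                c = datasets.get((window, "control", comp))
                t = datasets.get((window, "drought", comp))
                if c is not None and t is not None:
                    strata[comp] = (c, t)
            if strata:
                sg = correlations.sgh_contrast(
                    strata, kingdoms, n_perm=config.n_perm, seed=int(rng_seeds[2])
                )
                sg["window"] = window
                sgh_frames.append(sg)
        if sgh_frames:
            pd.concat(sgh_frames, ignore_index=True).to_csv(
                outdir / "sgh_contrast.tsv", sep="\t", index=False
            )

        stage = "networks"
        netdir = outdir / "networks"
        nets = {}
        for key, recs in all_records.items():
            net = networks.build_network(
                recs, data.taxonomy, config.rho_min, config.q_max
            )
            nets[key] = net
            networks.export_network(net, netdir / "_".join(key))
        comparisons = []
        for window in ("drought", "rewetting"):
            for comp in sorted(data.metadata["compartment"].unique()):
                nc = nets.get((window, "control", comp))
                nt = nets.get((window, "drought", comp))
                if nc is None or nt is None:
                    continue
                cmp_df = networks.compare_networks(nc, nt)
                cmp_df["window"], cmp_df["compartment"] = window, comp
                comparisons.append(cmp_df)
        if comparisons:
            pd.concat(comparisons, ignore_index=True).to_csv(
                outdir / "network_comparison.tsv", sep="\t", index=False
            )

        stage = "nulls"
        null_out = {
            "drought": nulls.autocorrelation_null(
                n_timepoints=6, n_iters=config.null_iters,
                rho_min=config.rho_min, q_max=config.q_max,
                seed=int(rng_seeds[3]),
            ),
            "rewetting": nulls.autocorrelation_null(
                n_timepoints=8, n_iters=config.null_iters,
                rho_min=config.rho_min, q_max=config.q_max,
                seed=int(rng_seeds[3]) + 1,
            ),
        }
        spatial_rows = []
        if config.spatial_check and {"x", "y"} <= set(data.metadata.columns):
            for key, net in nets.items():
                table = datasets[key]
                if net.number_of_edges() == 0:
                    continue
                res = nulls.spatial_link_attribution(
                    table, data.metadata, net, config.rho_min, config.q_max
                )
                if res is not None:
                    spatial_rows.append(
                        {
                            "window": key[0], "treatment": key[1],
                            "compartment": key[2],
                            "n_edges": res["n_edges"],
                            "n_spatial": res["n_spatial"],
                            "fraction_spatial": res["fraction_spatial"],
                        }
                    )
        (outdir / "nulls.json").write_text(json.dumps(null_out, indent=2))
        pd.DataFrame(spatial_rows).to_csv(
            outdir / "spatial_attribution.tsv", sep="\t", index=False
        )

        stage = "manifest"
        cfg = dataclasses.asdict(config)
        manifest = {
            "config": cfg,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage [{stage}]: {e}") from e
    return outdir


def report(run_dir: str | Path) -> str:
    """Assemble a plain-text summary from a completed run directory."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (no manifest.json)")
    lines = [f"# droughtnet run report: {run_dir}", ""]

    def section(title, path, cols=None):
        lines.append(f"## {title}")
        if not path.exists():
            lines.append("(missing — stage did not produce output)")
            lines.append("")
            return
        df = pd.read_csv(path, sep="\t")
        if cols:
            df = df[[c for c in cols if c in df.columns]]
        lines.append(df.to_string(index=False) if not df.empty else "(empty)")
        lines.append("")

    section(
        "Stability (resistance/resilience per compartment x kingdom x week)",
        run_dir / "stability.tsv",
        ["compartment", "kingdom", "resolution", "phase", "week",
         "statistic", "resilience", "p_bonferroni", "significant"],
    )
    section("Kingdom contrasts", run_dir / "stability_kingdom_contrasts.tsv")
    section("Correlation summaries", run_dir / "correlation_summaries.tsv",
            ["window", "treatment", "compartment", "link_class",
             "mean_combined", "fraction_positive", "n_pairs"])
    section("Stress-gradient contrast", run_dir / "sgh_contrast.tsv")
    section("Network comparison (treatment - control)",
            run_dir / "network_comparison.tsv")
    section("Spatial link attribution", run_dir / "spatial_attribution.tsv")
    if (run_dir / "nulls.json").exists():
        lines.append("## Temporal-autocorrelation null")
        lines.append((run_dir / "nulls.json").read_text())
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text)
    return text
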