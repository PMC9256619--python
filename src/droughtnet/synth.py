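"""Synthetic two-kingdom longitudinal community data with known planted effects.

Emulates a field drought/rewetting experiment: two irrigation treatments
(control; drought during a pre-flowering window followed by rewetting),
replicate plots sampled weekly across four plant compartments, with paired
bacterial (16S) and fungal (ITS) OTU count tables drawn from the same
physical samples.

The generator is a latent-Gaussian copula: per-sample latent vectors carry
planted correlation blocks (within and between kingdoms, switched on or off
by the sample's stress condition), a per-taxon log-normal baseline plus a
treatment-by-week compositional shift that differs between kingdoms, and a
multinomial read draw at a log-normally distributed library size.  Every
planted effect is therefore known exactly, so downstream detectors can be
tested for recovery and for calibration under the null.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "CorrelationBlock",
    "EffectSpec",
    "SynthDataset",
    "generate_metadata",
    "generate_counts",
    "generate_random_walks",
    "write_dataset",
]

COMPARTMENTS = ("leaf", "root", "rhizosphere", "soil")

_BACTERIAL_PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Firmicutes",
    "Bacteroidetes",
    "Chloroflexi",
    "Acidobacteria",
)
_FUNGAL_FAMILIES = (
    "Mortierellaceae",
    "Chaetomiaceae",
    "Nectriaceae",
    "Glomeraceae",
    "Claroideoglomeraceae",
    "Aspergillaceae",
    "Pleosporaceae",
    "Hypocreaceae",
)
_FUNGAL_GUILDS = ("saprotroph", "plant_pathogen", "endophyte", "unassigned")


def _default_plot_coordinates(n_plots_total: int) -> dict[str, tuple[float, float]]:
    """Lay plots out on a grid of 16 x 8 m cells, 4 columns per row."""
    coords = {}
    for i in range(n_plots_total):
        row, col = divmod(i, 4)
        coords[f"P{i + 1}"] = (col * 16.0 + 8.0, row * 8.0 + 4.0)
    return coords


@dataclass(frozen=True)
class DesignSpec:
    """Experimental layout: treatments, plots, compartments and weeks.

    ``drought_window`` is the inclusive week interval during which the
    drought treatment is unwatered; ``rewet_window`` the inclusive interval
    after watering resumes.  Control plots are sampled over all weeks; the
    drought treatment is sampled from the first drought week onward.
    """

    n_plots_per_treatment: int = 6
    weeks: tuple[int, ...] = tuple(range(1, 18))
    drought_window: tuple[int, int] = (3, 8)
    rewet_window: tuple[int, int] = (9, 17)
    compartments: tuple[str, ...] = COMPARTMENTS
    plot_coordinates: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if self.n_plots_per_treatment < 2:
            raise ValueError("need at least 2 plots per treatment")
        d0, d1 = self.drought_window
        r0, r1 = self.rewet_window
        if not (d0 <= d1 < r0 <= r1):
            raise ValueError(
                "drought_window and rewet_window must be ordered and disjoint"
            )
        if self.plot_coordinates is not None:
            seen = set(self.plot_coordinates.values())
            if len(seen) != len(self.plot_coordinates):
                raise ValueError("plot coordinates must be distinct per plot")

    @property
    def control_plots(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_plots_per_treatment)]

    @property
    def drought_plots(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_plots_per_treatment)]

    def coordinates(self) -> dict[str, tuple[float, float]]:
        if self.plot_coordinates is not None:
            return dict(self.plot_coordinates)
        grid = _default_plot_coordinates(2 * self.n_plots_per_treatment)
        # randomized-block layout: alternate treatments across the grid so
        # plot position is not confounded with treatment
        plots = [
            p
            for pair in zip(self.control_plots, self.drought_plots)
            for p in pair
        ]
        return {p: xy for p, xy in zip(plots, grid.values())}


@dataclass(frozen=True)
class CorrelationBlock:
    """A planted equicorrelated taxon block.

    ``link_class`` decides which kingdoms the member taxa are drawn from
    (BB: all bacteria; FF: all fungi; BF: half each).  ``condition``
    controls when the block's latent correlation is active:

    - ``"always"``     — every sample,
    - ``"unstressed"`` — every sample except drought-treatment samples
      during the drought window (an association disrupted by stress),
    - ``"stressed"``   — only drought-treatment samples during the drought
      window (an association created by stress).

    ``compartments`` restricts activity to the listed compartments
    (``None`` = all).
    """

    size: int
    latent_rho: float
    link_class: str
    condition: str = "always"
    compartments: tuple[str, ...] | None = None

    def __post_init__(self):
        if not (-1.0 < self.latent_rho < 1.0):
            raise ValueError("target latent correlation must lie in (-1, 1)")
        if self.link_class not in ("BB", "FF", "BF"):
            raise ValueError(f"unknown link class {self.link_class!r}")
        if self.condition not in ("always", "unstressed", "stressed"):
            raise ValueError(f"unknown block condition {self.condition!r}")
        if self.size < 2:
            raise ValueError("block needs at least 2 taxa")
        # equicorrelated matrix is PSD only for rho > -1/(k-1)
        if self.latent_rho <= -1.0 / (self.size - 1):
            raise ValueError("latent_rho too negative for block size (not PSD)")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect sizes: what the pipeline should recover.

    Drought shifts are log-scale loadings multiplying a fixed per-taxon
    response direction; the kingdom asymmetry (bacteria shifted more,
    bacteria recovering faster) encodes the hypothesis that fungi resist
    drought better while bacteria rebound faster after rewetting.
    ``stress_factor_loading`` scales a shared latent factor applied, in
    stressed samples only, to a fixed random subset of taxa
    (``stress_factor_fraction`` of each table).  Because the member taxa
    move together it raises the frequency of positive pairwise
    correlations under drought (the stress-gradient signal) while its
    pairwise latent correlation, loading^2 / (1 + loading^2), stays below
    the strong-edge threshold of the network analysis.
    """

    kingdom_drought_shift: dict[str, float] = field(
        default_factory=lambda: {"bacteria": 1.2, "fungi": 0.6}
    )
    kingdom_recovery_rate: dict[str, float] = field(
        default_factory=lambda: {"bacteria": 0.8, "fungi": 0.15}
    )
    correlation_blocks: tuple[CorrelationBlock, ...] = (
        CorrelationBlock(8, 0.85, "BB", condition="unstressed"),
        CorrelationBlock(6, 0.90, "BF", condition="unstressed"),
        CorrelationBlock(6, 0.85, "FF", condition="stressed",
                         compartments=("rhizosphere",)),
    )
    stress_factor_loading: float = 0.9
    stress_factor_fraction: float = 0.4
    baseline_log_sd: float = 1.0
    n_spatial_bacteria: int = 0
    n_spatial_fungi: int = 0
    spatial_gradient: float = 2.0
    depth_lognormal: tuple[float, float] = (math.log(25_000.0), 0.15)
    amf_fraction: float = 0.08

    def __post_init__(self):
        for d in (self.kingdom_drought_shift, self.kingdom_recovery_rate):
            for k, v in d.items():
                if not math.isfinite(v):
                    raise ValueError(f"effect size for {k} must be finite")

    @classmethod
    def null(cls) -> "EffectSpec":
        """All effects zeroed: samples exchangeable across treatments."""
        return cls(
            kingdom_drought_shift={"bacteria": 0.0, "fungi": 0.0},
            kingdom_recovery_rate={"bacteria": 0.0, "fungi": 0.0},
            correlation_blocks=(),
            stress_factor_loading=0.0,
            n_spatial_bacteria=0,
            n_spatial_fungi=0,
        )


def generate_metadata(design: DesignSpec) -> pd.DataFrame:
    """One sample row per (treatment, plot, compartment, week).

    Control plots span all design weeks; drought plots are sampled from the
    first drought week onward.  Returns a DataFrame indexed by sample id
    with columns treatment, plot, compartment, week, x, y.
    """
    if set(design.control_plots) & set(design.drought_plots):
        raise ValueError("plot identifiers overlap across treatments")
    coords = design.coordinates()
    first_drought = design.drought_window[0]
    rows = []
    for treatment, plots in (
        ("control", design.control_plots),
        ("drought", design.drought_plots),
    ):
        weeks = [
            w for w in design.weeks if treatment == "control" or w >= first_drought
        ]
        for plot in plots:
            x, y = coords[plot]
            for comp in design.compartments:
                for week in weeks:
                    rows.append(
                        {
                            "sample_id": f"{treatment[:1].upper()}_{plot}_{comp}_w{week:02d}",
                            "treatment": treatment,
                            "plot": plot,
                            "compartment": comp,
                            "week": week,
                            "x": x,
                            "y": y,
                        }
                    )
    meta = pd.DataFrame(rows)
    if not meta.empty:
        meta = meta.set_index("sample_id")
    else:
        meta.index.name = "sample_id"
    return meta


def _assign_block_taxa(
    blocks: tuple[CorrelationBlock, ...], bact_ids: list[str], fungi_ids: list[str]
) -> list[np.ndarray]:
    """Pick member taxa for each block, non-overlapping, from the front of
    each kingdom's id list."""
    next_b, next_f = 0, 0
    all_ids = bact_ids + fungi_ids
    index = {t: i for i, t in enumerate(all_ids)}
    members = []
    for blk in blocks:
        if blk.link_class == "BB":
            take_b, take_f = blk.size, 0
        elif blk.link_class == "FF":
            take_b, take_f = 0, blk.size
        else:
            take_b = blk.size // 2
            take_f = blk.size - take_b
        if next_b + take_b > len(bact_ids) or next_f + take_f > len(fungi_ids):
            raise ValueError("not enough taxa to host all correlation blocks")
        ids = bact_ids[next_b : next_b + take_b] + fungi_ids[next_f : next_f + take_f]
        next_b += take_b
        next_f += take_f
        members.append(np.array([index[t] for t in ids], dtype=int))
    return members


@dataclass
class SynthDataset:
    """Paired count tables plus taxonomy and sample metadata."""

    bacteria: pd.DataFrame  # samples x bacterial taxa, integer counts
    fungi: pd.DataFrame  # samples x fungal taxa, integer counts
    taxonomy: pd.DataFrame  # indexed by taxon id
    metadata: pd.DataFrame  # indexed by sample id
    params: dict = field(default_factory=dict)


def generate_counts(
    design: DesignSpec,
    effects: EffectSpec,
    n_bacteria: int = 200,
    n_fungi: int = 100,
    seed: int = 0,
) -> SynthDataset:
    """Draw paired 16S/ITS count tables under the design with planted effects.

    Per sample: a latent Gaussian vector with the active block correlation
    structure, plus the stress factor when the sample is stressed; log
    abundance = per-taxon log-normal baseline + 0.8 x latent + drought
    shift (decaying exponentially after rewetting at the kingdom recovery
    rate) + spatial gradient term; counts are a multinomial draw per
    kingdom at a log-normal library size.  Deterministic given ``seed``.
    """
    if n_bacteria < 10 or n_fungi < 10:
        raise ValueError("need at least 10 taxa per kingdom")
    rng = np.random.default_rng(seed)
    meta = generate_metadata(design)

    bact_ids = [f"bOTU{i + 1:04d}" for i in range(n_bacteria)]
    fungi_ids = [f"fOTU{i + 1:04d}" for i in range(n_fungi)]
    all_ids = bact_ids + fungi_ids
    n_taxa = len(all_ids)
    kingdoms = np.array(["bacteria"] * n_bacteria + ["fungi"] * n_fungi)

    # Per-taxon fixed parameters.
    baseline = rng.normal(0.0, effects.baseline_log_sd, size=n_taxa)
    response = rng.normal(0.0, 1.0, size=n_taxa)  # drought response direction
    # equal loadings on a fixed subset: the factor pushes member taxa up
    # together, which survives compositional closure (a uniform shift over
    # all taxa would cancel in the softmax)
    stress_loadings = (
        rng.random(n_taxa) < effects.stress_factor_fraction
    ).astype(float)
    block_taxa = _assign_block_taxa(effects.correlation_blocks, bact_ids, fungi_ids)
    for blk, idx in zip(effects.correlation_blocks, block_taxa):
        # tight blocks (meant to yield strong-edge co-occurrences) sit on
        # common taxa so rank correlations survive the multinomial read
        # noise; diffuse low-rho blocks are left at their drawn baselines
        if blk.latent_rho >= 0.6:
            baseline[idx] = np.maximum(baseline[idx], 1.0)

    # Spatial taxa: last taxa of each kingdom, following the x coordinate.
    spatial_idx = np.concatenate(
        [
            np.arange(n_bacteria - effects.n_spatial_bacteria, n_bacteria),
            np.arange(n_taxa - effects.n_spatial_fungi, n_taxa),
        ]
    ).astype(int)

    xs = meta["x"].to_numpy(float)
    x_scale = max(xs.std(), 1e-9)

    # Taxonomy.
    phyla = rng.choice(_BACTERIAL_PHYLA, size=n_bacteria).astype(object)
    families = rng.choice(_FUNGAL_FAMILIES, size=n_fungi).astype(object)
    n_amf = int(round(effects.amf_fraction * n_fungi))
    amf = np.zeros(n_fungi, dtype=bool)
    amf[rng.choice(n_fungi, size=n_amf, replace=False)] = True
    guilds = rng.choice(_FUNGAL_GUILDS, size=n_fungi).astype(object)
    guilds[amf] = "arbuscular_mycorrhizal"
    taxonomy = pd.DataFrame(
        {
            "kingdom": kingdoms,
            "phylum": np.concatenate([phyla, np.full(n_fungi, "")]),
            "family": np.concatenate([np.full(n_bacteria, ""), families]),
            "guild": np.concatenate([np.full(n_bacteria, ""), guilds]),
            "amf": np.concatenate([np.zeros(n_bacteria, bool), amf]),
        },
        index=pd.Index(all_ids, name="taxon_id"),
    )

    d0, d1 = design.drought_window
    shift = np.array([effects.kingdom_drought_shift[k] for k in kingdoms])
    rate = np.array([effects.kingdom_recovery_rate[k] for k in kingdoms])

    depth_mu, depth_sd = effects.depth_lognormal
    counts = np.zeros((len(meta), n_taxa), dtype=np.int64)
    depths_b = np.rint(rng.lognormal(depth_mu, depth_sd, size=len(meta))).astype(int)
    depths_f = np.rint(rng.lognormal(depth_mu, depth_sd, size=len(meta))).astype(int)
    if (depths_b <= 0).any() or (depths_f <= 0).any():
        raise ValueError("non-positive library size drawn; check depth_lognormal")

    is_b = kingdoms == "bacteria"
    is_f = ~is_b

    for i, (sid, row) in enumerate(meta.iterrows()):
        stressed = row["treatment"] == "drought" and d0 <= row["week"] <= d1
        z = rng.standard_normal(n_taxa)
        for blk, idx in zip(effects.correlation_blocks, block_taxa):
            active = (
                blk.condition == "always"
                or (blk.condition == "stressed" and stressed)
                or (blk.condition == "unstressed" and not stressed)
            )
            if blk.compartments is not None and row["compartment"] not in blk.compartments:
                active = False
            if not active:
                continue
            # equicorrelated draw: sqrt(rho) * shared + sqrt(1-rho) * own
            r = blk.latent_rho
            shared = rng.standard_normal()
            z[idx] = math.sqrt(r) * shared + math.sqrt(1.0 - r) * z[idx]
        if stressed and effects.stress_factor_loading:
            z = z + (
                effects.stress_factor_loading
                * stress_loadings
                * rng.standard_normal()
            )

        # drought shift with exponential post-rewetting decay
        if row["treatment"] == "drought":
            if row["week"] <= d1:
                decay = 1.0 if row["week"] >= d0 else 0.0
                decay = np.full(n_taxa, decay)
            else:
                decay = np.exp(-rate * (row["week"] - d1))
        else:
            decay = np.zeros(n_taxa)

        log_lam = baseline + 0.8 * z + shift * response * decay
        if len(spatial_idx):
            log_lam[spatial_idx] += (
                effects.spatial_gradient * (row["x"] - xs.mean()) / x_scale
            )

        for mask, depth in ((is_b, depths_b[i]), (is_f, depths_f[i])):
            lam = log_lam[mask]
            p = np.exp(lam - lam.max())
            p /= p.sum()
            counts[i, mask] = rng.multinomial(depth, p)

    bact = pd.DataFrame(counts[:, is_b], index=meta.index, columns=bact_ids)
    fung = pd.DataFrame(counts[:, is_f], index=meta.index, columns=fungi_ids)
    params = {
        "seed": seed,
        "n_bacteria": n_bacteria,
        "n_fungi": n_fungi,
        "design": dataclasses.asdict(design),
        "effects": dataclasses.asdict(effects),
    }
    return SynthDataset(bact, fung, taxonomy, meta, params)


def generate_random_walks(
    n_taxa: int, n_timepoints: int, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Independent Gaussian random walks, ``n_replicates`` per taxon.

    Walks start at 0 and accumulate standard-normal increments; taxa are
    mutually independent by construction, so any correlation detected
    among them downstream is a temporal-autocorrelation artifact.  Returns
    a long-format frame (taxon, replicate, t, value).
    """
    if min(n_taxa, n_timepoints, n_replicates) < 2:
        raise ValueError("all counts must be at least 2")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_taxa, n_replicates, n_timepoints))
    walks = steps.cumsum(axis=2)
    taxon, rep, t = np.meshgrid(
        np.arange(n_taxa), np.arange(n_replicates), np.arange(n_timepoints),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "taxon": taxon.ravel(),
            "replicate": rep.ravel(),
            "t": t.ravel(),
            "value": walks.ravel(),
        }
    )


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> Path:
    """Emit tables as TSV plus a manifest recording seed and parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.bacteria.to_csv(outdir / "counts_16S.tsv", sep="\t")
    dataset.fungi.to_csv(outdir / "counts_ITS.tsv", sep="\t")
    dataset.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    dataset.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    (outdir / "manifest.json").write_text(json.dumps(dataset.params, indent=2))
    return outdir
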