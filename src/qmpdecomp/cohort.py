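"""Synthetic decomposition cohorts with known ground truth.

The generator emulates a buried-carcass decomposition study: carcasses
exhumed on days 1, 3, 7, 14, 21, 28 and 35 post-burial, six replicates per
day, three sample types (regular soil sampled from day 0, grave soil and
carcass tissue from day 1), bacteria and fungi profiled separately, and a
tissue metabolome.  That design yields 132 samples: 48 regular soil,
42 grave soil and 42 tissue.

Each taxon follows a piecewise log-linear trajectory of true gene copies
per gram: a baseline log10 load, a growth rate up to a breakpoint day
(default 14, the peak of putrefaction) and a second rate afterwards.
Per-sample multiplicative lognormal noise (default 0.2 log10 units) is
applied on top, reads are drawn multinomially in proportion to
(copies per gram x sample mass) jointly with the spike-in copies, and
metabolite intensities are lognormal with planted PMI trends and
taxon-driven features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import SpikeInDesign
from .core import (
    DOMAINS,
    SAMPLE_TYPES,
    AbundanceMatrix,
    GroundTruth,
    check_metadata,
    subseeds,
)
from .metabolomics import MetaboliteMatrix

logger = logging.getLogger("qmpdecomp")

_TYPE_PREFIX = {"regular_soil": "RS", "grave_soil": "GS", "tissue": "TS"}

#: mass ranges in grams, mirroring ~0.5 g of soil / 0.2 g of tissue per extract
_MASS_RANGE = {"regular_soil": (0.3, 0.7), "grave_soil": (0.3, 0.7), "tissue": (0.15, 0.25)}

_BACT_PHYLA = ("Pseudomonadota", "Bacillota", "Actinomycetota", "Bacteroidota", "Acidobacteriota", "Chloroflexota")
_BACT_PHYLUM_W = (0.30, 0.25, 0.20, 0.15, 0.05, 0.05)
_FUNG_PHYLA = ("Ascomycota", "Basidiomycota", "Mucoromycota", "Mortierellomycota")
_FUNG_PHYLUM_W = (0.50, 0.30, 0.10, 0.10)

#: named after genera repeatedly reported as carrion decomposers
_BACT_DECOMPOSER_NAMES = (
    "Sporosarcina", "Paenalcaligenes", "Vagococcus", "Morganella", "Psychrobacter",
    "Proteus", "Tissierella", "Enterococcus", "Clostridium", "Microbacterium",
    "Ignatzschineria", "Savagea", "Oblitimonas", "Peptoniphilus",
)
_FUNG_DECOMPOSER_NAMES = (
    "Scopulariopsis", "Pseudogymnoascus", "Fusarium", "Chrysosporium",
    "Mortierella", "Candida", "Yarrowia", "Dipodascus", "Mucor", "Trichosporon",
)

_METABOLITE_CLASSES = (
    "Lipids and lipid-like molecules",
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Benzenoids",
    "Nucleosides, nucleotides, and analogues",
    "Organic oxygen compounds",
    "Organic nitrogen compounds",
    "Phenylpropanoids and polyketides",
    "Alkaloids and derivatives",
)


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: exhumation days, replication, and profiling depth."""

    days: tuple[int, ...] = (1, 3, 7, 14, 21, 28, 35)
    regular_soil_days: tuple[int, ...] = (0, 1, 3, 7, 14, 21, 28, 35)
    replicates_per_day: int = 6
    sample_types: tuple[str, ...] = SAMPLE_TYPES
    n_bacterial_taxa: int = 300
    n_fungal_taxa: int = 150
    read_depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        for days in (self.days, self.regular_soil_days):
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("days must be strictly increasing")
        if self.replicates_per_day < 2:
            raise ValueError("need at least 2 replicates per day")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        unknown = set(self.sample_types) - set(SAMPLE_TYPES)
        if unknown:
            raise ValueError(f"unknown sample types: {sorted(unknown)}")

    def n_samples(self) -> int:
        n = 0
        for stype in self.sample_types:
            days = self.regular_soil_days if stype == "regular_soil" else self.days
            n += len(days) * self.replicates_per_day
        return n


@dataclass
class TaxonDynamics:
    """Per-taxon, per-sample-type piecewise log-linear load trajectories.

    ``table`` is indexed by (taxon, sample_type) with columns ``base_log10``
    (log10 copies per gram at day 0), ``rate_early`` and ``rate_late``
    (log10/day before and after ``breakpoint_day``).  ``decomposer`` flags
    taxa whose tissue trajectory is monotone increasing with PMI.  ``guild``
    optionally assigns taxa to a guild sharing a per-sample latent factor of
    scale ``guild_sigma`` (log10 units) — coordinated day-to-day responses
    within a decomposer guild, used to plant co-occurrence module structure.
    """

    table: pd.DataFrame
    decomposer: pd.Series
    breakpoint_day: float = 14.0
    guild: pd.Series | None = None
    guild_sigma: float = 0.0

    def __post_init__(self) -> None:
        need = {"base_log10", "rate_early", "rate_late"}
        if not need <= set(self.table.columns):
            raise ValueError(f"dynamics table needs columns {sorted(need)}")
        reg = self.table[self.table.index.get_level_values(1) == "regular_soil"]
        if len(reg):
            horizon = 35.0
            net = reg["rate_early"] * min(self.breakpoint_day, horizon) + reg["rate_late"] * max(
                0.0, horizon - self.breakpoint_day
            )
            if (net.abs() >= 0.5).any():
                raise ValueError("regular_soil trajectories must satisfy |net log10 change| < 0.5")

    @property
    def taxa(self) -> pd.Index:
        return self.table.index.get_level_values(0).unique()

    @property
    def sample_types(self) -> set[str]:
        return set(self.table.index.get_level_values(1))

    def trajectory_log10(self, sample_type: str, days: np.ndarray) -> pd.DataFrame:
        """Expected log10 copies/g, taxa x len(days), before noise."""
        sub = self.table.xs(sample_type, level=1)
        days = np.asarray(days, dtype=float)
        early = np.minimum(days, self.breakpoint_day)
        late = np.maximum(days - self.breakpoint_day, 0.0)
        traj = (
            sub["base_log10"].to_numpy()[:, None]
            + sub["rate_early"].to_numpy()[:, None] * early[None, :]
            + sub["rate_late"].to_numpy()[:, None] * late[None, :]
        )
        return pd.DataFrame(traj, index=sub.index, columns=pd.RangeIndex(len(days)))


@dataclass
class Cohort:
    """A fully simulated cohort: truth, read counts, spikes, metabolome."""

    design: CohortDesign
    metadata: pd.DataFrame
    truth: GroundTruth
    counts: dict[str, AbundanceMatrix]
    spikes: dict[str, SpikeInDesign]
    taxonomy: pd.DataFrame
    metabolites: MetaboliteMatrix | None = None
    dynamics: dict[str, TaxonDynamics] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metadata & dynamics construction


def build_metadata(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Sample sheet: IDs, type, PMI day, replicate and extract mass (g)."""
    rng = np.random.default_rng(seed)
    rows = []
    for stype in design.sample_types:
        days = design.regular_soil_days if stype == "regular_soil" else design.days
        lo, hi = _MASS_RANGE[stype]
        for day in days:
            for rep in range(1, design.replicates_per_day + 1):
                rows.append(
                    {
                        "sample_id": f"{_TYPE_PREFIX[stype]}{day:02d}R{rep}",
                        "sample_type": stype,
                        "day": day,
                        "replicate": rep,
                        "mass_g": round(float(rng.uniform(lo, hi)), 4),
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return check_metadata(meta)


def _taxon_names(domain: str, n: int, decomposer_names: Sequence[str], n_decomposers: int) -> list[str]:
    if n_decomposers > len(decomposer_names) or n_decomposers > n:
        raise ValueError("more decomposers requested than available names/taxa")
    prefix = "Bact" if domain == "bacteria" else "Fung"
    generic = [f"{prefix}Genus{i:03d}" for i in range(1, n - n_decomposers + 1)]
    return list(decomposer_names[:n_decomposers]) + generic


def default_dynamics(
    design: CohortDesign,
    n_bact_decomposers: int = 14,
    n_fung_decomposers: int = 10,
    seed: int | None = None,
) -> dict[str, TaxonDynamics]:
    """The default study conditions: a nutrient-flush tissue bloom.

    Regular soil is stable; grave soil rises transiently then declines;
    in tissue both domains proliferate rapidly to day 14 (total load up
    >= 2 orders of magnitude), after which bacteria plateau and fungi
    decline.  Planted decomposers (14 bacterial, 10 fungal) are the
    strongest monotone risers in tissue.
    """
    seed = design.seed if seed is None else seed
    s_b, s_f = subseeds(seed, 2)
    out = {}
    for domain, n_taxa, names, n_dec, sd in (
        ("bacteria", design.n_bacterial_taxa, _BACT_DECOMPOSER_NAMES, n_bact_decomposers, s_b),
        ("fungi", design.n_fungal_taxa, _FUNG_DECOMPOSER_NAMES, n_fung_decomposers, s_f),
    ):
        if n_taxa == 0:
            continue
        n_dec = min(n_dec, n_taxa)
        rng = np.random.default_rng(sd)
        taxa = _taxon_names(domain, n_taxa, names, n_dec)
        is_dec = np.zeros(n_taxa, dtype=bool)
        is_dec[:n_dec] = True
        recs = {}
        base_soil = rng.normal(5.0 if domain == "bacteria" else 4.6, 0.6, n_taxa)
        if "regular_soil" in design.sample_types:
            recs["regular_soil"] = (
                base_soil,
                np.clip(rng.normal(0.0, 0.006, n_taxa), -0.01, 0.01),
                np.clip(rng.normal(0.0, 0.006, n_taxa), -0.01, 0.01),
            )
        if "grave_soil" in design.sample_types:
            if domain == "bacteria":
                re_, rl = rng.normal(0.08, 0.025, n_taxa), rng.normal(-0.04, 0.015, n_taxa)
            else:
                re_, rl = rng.normal(0.06, 0.02, n_taxa), rng.normal(-0.05, 0.015, n_taxa)
            recs["grave_soil"] = (base_soil + rng.normal(0.0, 0.1, n_taxa), re_, rl)
        if "tissue" in design.sample_types:
            base_t = rng.normal(4.6 if domain == "bacteria" else 4.2, 0.6, n_taxa)
            if domain == "bacteria":
                re_ = rng.normal(0.15, 0.035, n_taxa)
                rl = rng.normal(0.01, 0.01, n_taxa)
                re_[is_dec] = rng.normal(0.20, 0.015, n_dec)
                rl[is_dec] = np.abs(rng.normal(0.03, 0.005, n_dec))
            else:
                re_ = rng.normal(0.13, 0.035, n_taxa)
                rl = rng.normal(-0.06, 0.02, n_taxa)
                re_[is_dec] = rng.normal(0.18, 0.015, n_dec)
                rl[is_dec] = np.abs(rng.normal(0.02, 0.005, n_dec))
            recs["tissue"] = (base_t, re_, rl)
        out[domain] = _assemble_dynamics(taxa, recs, is_dec)
    return out


def _assemble_dynamics(
    taxa: Sequence[str],
    per_type: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    is_decomposer: np.ndarray,
    guild: pd.Series | None = None,
    guild_sigma: float = 0.0,
) -> TaxonDynamics:
    frames = []
    for stype, (base, re_, rl) in per_type.items():
        frames.append(
            pd.DataFrame(
                {"base_log10": base, "rate_early": re_, "rate_late": rl},
                index=pd.MultiIndex.from_product([taxa, [stype]], names=["taxon", "sample_type"]),
            )
        )
    table = pd.concat(frames).sort_index()
    dec = pd.Series(np.asarray(is_decomposer, dtype=bool), index=pd.Index(taxa, name="taxon"))
    return TaxonDynamics(table=table, decomposer=dec, guild=guild, guild_sigma=guild_sigma)


def make_taxonomy(dynamics: Mapping[str, TaxonDynamics], seed: int = 0) -> pd.DataFrame:
    """Genus/phylum table for all simulated taxa (taxon IDs are genus-level)."""
    rng = np.random.default_rng(seed)
    rows = []
    for domain, dyn in dynamics.items():
        phyla, w = (_BACT_PHYLA, _BACT_PHYLUM_W) if domain == "bacteria" else (_FUNG_PHYLA, _FUNG_PHYLUM_W)
        for taxon in dyn.taxa:
            rows.append(
                {
                    "taxon": taxon,
                    "genus": taxon,
                    "phylum": rng.choice(phyla, p=w),
                    "domain": domain,
                    "decomposer": bool(dyn.decomposer.get(taxon, False)),
                }
            )
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# simulation operations


def simulate_true_loads(
    design: CohortDesign,
    dynamics: Mapping[str, TaxonDynamics],
    seed: int,
    noise_sigma: float = 0.2,
    metadata: pd.DataFrame | None = None,
) -> GroundTruth:
    """Draw true copies-per-gram matrices for every domain.

    Per-sample replicate noise is multiplicative lognormal:
    10**Normal(0, noise_sigma) on each (taxon, sample) load.  Deterministic
    given ``seed``; with ``noise_sigma=0`` the loads equal the trajectory
    values exactly.
    """
    meta_seed, *domain_seeds = subseeds(seed, 1 + len(dynamics))
    if metadata is None:
        metadata = build_metadata(design, meta_seed)
    loads: dict[str, pd.DataFrame] = {}
    for (domain, dyn), dseed in zip(dynamics.items(), domain_seeds):
        missing = set(metadata["sample_type"]) - dyn.sample_types
        if missing:
            raise ValueError(f"{domain}: dynamics define no trajectory for sample types {sorted(missing)}")
        rng = np.random.default_rng(dseed)
        cols = {}
        guild_codes = None
        if dyn.guild is not None and dyn.guild_sigma > 0:
            guild_codes = dyn.guild.reindex(dyn.taxa).fillna("")
        for sample_id, row in metadata.iterrows():
            traj = dyn.trajectory_log10(row["sample_type"], np.array([row["day"]])).iloc[:, 0]
            log_load = traj + rng.normal(0.0, noise_sigma, len(traj)) if noise_sigma > 0 else traj.copy()
            if guild_codes is not None:
                for g in guild_codes.unique():
                    if g:
                        u = rng.normal(0.0, dyn.guild_sigma)
                        log_load[guild_codes.to_numpy() == g] += u
            cols[sample_id] = 10.0 ** log_load
        loads[domain] = pd.DataFrame(cols, index=pd.Index(dyn.taxa, name="taxon")).reindex(
            columns=metadata.index
        )
    return GroundTruth(metadata=metadata, loads=loads)


def dose_spikes(
    truth: GroundTruth,
    domain: str,
    levels: tuple[float, ...] = (0.002, 0.02, 0.2),
    measurement_sigma: float = 0.1,
    seed: int = 0,
) -> SpikeInDesign:
    """Spike-in input copies per sample: a gradient dosed per DNA extract.

    Spikes are added to each quantified extract at ``levels`` fractions of
    the fluorometrically measured total copy number (truth perturbed by
    ``measurement_sigma`` log10 units of quantification noise), giving a
    known per-sample copy gradient spanning two orders of magnitude.
    """
    rng = np.random.default_rng(seed)
    extract_copies = truth.total_load(domain) * truth.metadata["mass_g"]
    measured = extract_copies * 10.0 ** rng.normal(0.0, measurement_sigma, len(extract_copies))
    tag = "B" if domain == "bacteria" else "F"
    table = pd.DataFrame(
        {s: [lvl * measured[s] for lvl in levels] for s in truth.metadata.index},
        index=pd.Index([f"SPIKE_{tag}{i + 1}" for i in range(len(levels))], name="spike_id"),
    )
    return SpikeInDesign(table=table)


def simulate_reads(
    truth: GroundTruth,
    spikes: SpikeInDesign,
    depth: int,
    seed: int,
    domain: str = "bacteria",
) -> AbundanceMatrix:
    """Multinomial read counts for one domain, spike-in rows appended.

    Per sample, ``depth`` reads are distributed with probabilities
    proportional to (taxon copies/g x extract mass) and spike-in input
    copies jointly.  Orientation: taxa rows x sample columns.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    loads = truth.loads[domain]
    if (spikes.table.to_numpy() <= 0).any():
        raise ValueError("spike copies must be strictly positive for every sample")
    missing = loads.columns.difference(spikes.table.columns)
    if len(missing):
        raise ValueError(f"spike design missing samples: {list(missing)[:5]}")
    rng = np.random.default_rng(seed)
    index = loads.index.append(spikes.table.index)
    out = np.zeros((len(index), loads.shape[1]), dtype=np.int64)
    if depth == 0:
        logger.warning("simulate_reads called with depth=0: returning all-zero matrix")
    else:
        masses = truth.metadata["mass_g"]
        for j, sample in enumerate(loads.columns):
            w = np.concatenate(
                [loads[sample].to_numpy() * masses[sample], spikes.table[sample].to_numpy()]
            )
            out[:, j] = rng.multinomial(depth, w / w.sum())
    data = pd.DataFrame(out, index=index, columns=loads.columns)
    return AbundanceMatrix(data=data, mode="raw_reads", domain=domain)


def simulate_metabolites(
    truth: GroundTruth,
    n_features: int = 300,
    frac_pos: float = 0.25,
    seed: int = 0,
    frac_neg: float = 0.30,
    n_driven_bacteria: int = 20,
    n_driven_fungi: int = 8,
    driver_taxa: Mapping[str, Sequence[str]] | None = None,
    trend_noise_sigma: float = 0.15,
    driver_coef: float = 0.8,
    driver_noise_sigma: float = 0.1,
) -> MetaboliteMatrix:
    """Tissue metabolite features with planted PMI trends and microbial drivers.

    A ``frac_pos`` fraction of features is monotone increasing with PMI
    (mostly lipid-like superclasses, mirroring late-decomposition lipid
    accumulation), ``frac_neg`` monotone decreasing (organic-acid- and
    nucleoside-like, consumed early), and the remainder is noise.  Within
    the noise block, driven features are linear in a designated taxon's
    standardized log10 load plus noise; more bacterial than fungal drivers
    by default, so the bacterial community carries more metabolite signal.
    Also records trend signs and the driver map on ``truth``.
    """
    if n_features < 2:
        raise ValueError("need at least 2 metabolite features")
    if not 0.0 <= frac_pos <= 1.0 or not 0.0 <= frac_neg <= 1.0 or frac_pos + frac_neg > 1.0:
        raise ValueError("trend fractions must lie in [0, 1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    meta = truth.metadata
    tissue = meta.index[meta["sample_type"] == "tissue"]
    if len(tissue) == 0:
        raise ValueError("cohort has no tissue samples to profile")
    days = meta.loc[tissue, "day"].to_numpy(dtype=float)
    d_mid, d_span = (days.min() + days.max()) / 2.0, max(days.max() - days.min(), 1.0)

    n_pos = int(round(frac_pos * n_features))
    n_neg = int(round(frac_neg * n_features))
    n_noise = n_features - n_pos - n_neg
    n_driven = min(n_driven_bacteria + n_driven_fungi, n_noise)

    features = [f"M{i:04d}" for i in range(1, n_features + 1)]
    signs = np.concatenate([np.ones(n_pos), -np.ones(n_neg), np.zeros(n_noise)])

    # superclass labels: positives lipid-enriched, negatives organic-acid /
    # nucleoside-enriched, remainder drawn across all classes
    classes = np.empty(n_features, dtype=object)
    others = np.array(_METABOLITE_CLASSES)
    for i in range(n_features):
        u = rng.random()
        if signs[i] > 0:
            classes[i] = "Lipids and lipid-like molecules" if u < 0.40 else rng.choice(others[1:])
        elif signs[i] < 0:
            if u < 0.20:
                classes[i] = "Organic acids and derivatives"
            elif u < 0.40:
                classes[i] = "Nucleosides, nucleotides, and analogues"
            else:
                classes[i] = rng.choice(others[[0, 2, 3, 5, 6, 7, 8]])
        else:
            classes[i] = rng.choice(others)

    log_i = np.empty((n_features, len(tissue)))
    base = rng.normal(6.0, 0.5, n_features)
    trend_x = (days - d_mid) / d_span
    for i in range(n_features):
        if signs[i] != 0:
            k = rng.uniform(0.5, 1.5)
            log_i[i] = base[i] + signs[i] * k * trend_x + rng.normal(0.0, trend_noise_sigma, len(tissue))
        else:
            log_i[i] = base[i] + rng.normal(0.0, rng.uniform(0.1, 0.3), len(tissue))

    # driven features occupy the first slots of the noise block
    driver_map: dict[str, tuple[str, str]] = {}
    if n_driven > 0:
        pool: list[tuple[str, str]] = []
        for domain, want in (("bacteria", n_driven_bacteria), ("fungi", n_driven_fungi)):
            if domain not in truth.loads or want <= 0:
                continue
            if driver_taxa and domain in driver_taxa:
                taxa = list(driver_taxa[domain])
            else:
                lv = np.log10(truth.loads[domain][tissue])
                taxa = list(lv.var(axis=1).nlargest(max(1, want // 2)).index)
            pool.extend((domain, taxa[k % len(taxa)]) for k in range(want))
        for i, (domain, taxon) in zip(range(n_pos + n_neg, n_pos + n_neg + n_driven), pool):
            z = np.log10(truth.loads[domain].loc[taxon, tissue].to_numpy(dtype=float))
            z = (z - z.mean()) / (z.std() or 1.0)
            log_i[i] = base[i] + driver_coef * z + rng.normal(0.0, driver_noise_sigma, len(tissue))
            driver_map[features[i]] = (domain, taxon)

    data = pd.DataFrame(10.0 ** log_i, index=pd.Index(features, name="feature"), columns=tissue)
    truth.metabolite_trend_sign = pd.Series(signs, index=data.index, name="trend_sign")
    truth.driver_map = driver_map
    return MetaboliteMatrix(
        data=data,
        superclass=pd.Series(classes, index=data.index, name="superclass"),
        state="raw",
    )


def simulate_cohort(
    design: CohortDesign | None = None,
    dynamics: Mapping[str, TaxonDynamics] | None = None,
    noise_sigma: float = 0.2,
    n_metabolite_features: int = 300,
    with_metabolites: bool = True,
    seed: int | None = None,
) -> Cohort:
    """End-to-end simulation: loads -> spikes -> reads (-> metabolome)."""
    design = design or CohortDesign()
    seed = design.seed if seed is None else seed
    dynamics = dict(dynamics) if dynamics is not None else default_dynamics(design, seed=seed)
    s_truth, s_tax, s_metab, *s_dom = subseeds(seed, 3 + 2 * len(dynamics))
    truth = simulate_true_loads(design, dynamics, seed=s_truth, noise_sigma=noise_sigma)
    counts, spikes = {}, {}
    for k, domain in enumerate(dynamics):
        sp = dose_spikes(truth, domain, seed=s_dom[2 * k])
        spikes[domain] = sp
        counts[domain] = simulate_reads(truth, sp, design.read_depth, seed=s_dom[2 * k + 1], domain=domain)
    metabolites = None
    if with_metabolites and "tissue" in design.sample_types:
        drivers = {
            d: list(dyn.decomposer.index[dyn.decomposer])
            for d, dyn in dynamics.items()
            if dyn.decomposer.any()
        } or None
        metabolites = simulate_metabolites(
            truth, n_features=n_metabolite_features, seed=s_metab, driver_taxa=drivers
        )
    return Cohort(
        design=design,
        metadata=truth.metadata,
        truth=truth,
        counts=counts,
        spikes=spikes,
        taxonomy=make_taxonomy(dynamics, seed=s_tax),
        metabolites=metabolites,
        dynamics=dynamics,
    )


# ---------------------------------------------------------------------------
# scenario presets


def trap_dynamics(
    n_taxa: int = 120,
    n_focal: int = 1,
    growth_per_day: float = 2.0 / 34.0,
    seed: int = 0,
) -> dict[str, TaxonDynamics]:
    """The compositional trap: constant composition over a growing load.

    All background taxa grow at exactly ``growth_per_day`` log10/day (total
    load up ~100x across the study window, composition constant); ``n_focal``
    focal taxa hold constant absolute copies, so their *relative* abundance
    collapses while their absolute abundance is flat.  Tissue only.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"Focal{i:02d}" for i in range(1, n_focal + 1)] + [
        f"BactGenus{i:03d}" for i in range(1, n_taxa - n_focal + 1)
    ]
    base = rng.normal(5.0, 0.7, n_taxa)
    base[:n_focal] = rng.normal(6.5, 0.1, n_focal)  # focal taxa abundant enough to stay in the top-100 set
    re_ = np.full(n_taxa, growth_per_day)
    re_[:n_focal] = 0.0
    is_dec = np.zeros(n_taxa, dtype=bool)
    return {"bacteria": _assemble_dynamics(taxa, {"tissue": (base, re_, re_.copy())}, is_dec)}


def guild_dynamics(
    n_taxa: int = 120,
    n_fungal_taxa: int = 60,
    n_bact_decomposers: int = 14,
    n_fung_decomposers: int = 10,
    seed: int = 0,
) -> dict[str, TaxonDynamics]:
    """Guild-structured tissue dynamics for module-recovery checks.

    Decomposer guilds share a strong per-sample latent factor (0.45 log10
    units) on top of a moderate monotone trend, while background taxa are
    stable noise; within-guild correlations then clear the network edge
    threshold while cross-guild and background correlations do not.
    """
    s_b, s_f = subseeds(seed, 2)
    out = {}
    for domain, n, n_dec, names, sd in (
        ("bacteria", n_taxa, n_bact_decomposers, _BACT_DECOMPOSER_NAMES, s_b),
        ("fungi", n_fungal_taxa, n_fung_decomposers, _FUNG_DECOMPOSER_NAMES, s_f),
    ):
        rng = np.random.default_rng(sd)
        taxa = _taxon_names(domain, n, names, n_dec)
        is_dec = np.zeros(n, dtype=bool)
        is_dec[:n_dec] = True
        base = rng.normal(5.5, 0.4, n)
        base[:n_dec] = rng.normal(6.0, 0.2, n_dec)
        re_ = np.clip(rng.normal(0.0, 0.004, n), -0.008, 0.008)
        rl = np.clip(rng.normal(0.0, 0.004, n), -0.008, 0.008)
        re_[:n_dec], rl[:n_dec] = 0.05, 0.02
        guild = pd.Series("", index=pd.Index(taxa, name="taxon"))
        guild.iloc[:n_dec] = f"{domain}_decomposers"
        out[domain] = _assemble_dynamics(
            taxa, {"tissue": (base, re_, rl)}, is_dec, guild=guild, guild_sigma=0.45
        )
    return out


def stable_dynamics(
    n_bacterial_taxa: int = 60,
    n_fungal_taxa: int = 40,
    seed: int = 0,
) -> dict[str, TaxonDynamics]:
    """Tissue dynamics with no temporal trend in either domain.

    Sample-to-sample variation is pure lognormal replicate noise, so any
    microbe-metabolite association must flow through the planted driver
    map rather than a shared PMI trend — the clean background for
    concordance tests.
    """
    s_b, s_f = subseeds(seed, 2)
    out = {}
    for domain, n, sd in (("bacteria", n_bacterial_taxa, s_b), ("fungi", n_fungal_taxa, s_f)):
        if n == 0:
            continue
        rng = np.random.default_rng(sd)
        taxa = _taxon_names(domain, n, (), 0)
        base = rng.normal(5.0, 0.5, n)
        zero = np.zeros(n)
        out[domain] = _assemble_dynamics(taxa, {"tissue": (base, zero, zero.copy())}, np.zeros(n, bool))
    return out


def signal_dynamics(
    n_taxa: int = 100,
    n_informative: int = 5,
    seed: int = 0,
) -> dict[str, TaxonDynamics]:
    """Purely compositional PMI signal over a stable total load.

    ``n_informative`` low-abundance marker taxa trend monotonically with
    PMI (mixed signs) while the abundant background is stable, so the total
    load barely moves and QMP carries no information beyond composition.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"Marker{i:02d}" for i in range(1, n_informative + 1)] + [
        f"BactGenus{i:03d}" for i in range(1, n_taxa - n_informative + 1)
    ]
    base = rng.normal(5.5, 0.4, n_taxa)
    base[:n_informative] = rng.normal(4.3, 0.1, n_informative)
    re_ = np.clip(rng.normal(0.0, 0.003, n_taxa), -0.006, 0.006)
    signs = np.array([1, -1, 1, -1, 1] * (n_informative // 5 + 1))[:n_informative]
    re_[:n_informative] = signs * rng.uniform(0.05, 0.07, n_informative)
    is_dec = np.zeros(n_taxa, dtype=bool)
    return {"bacteria": _assemble_dynamics(taxa, {"tissue": (base, re_, re_.copy())}, is_dec)}


def tissue_design(seed: int = 0, read_depth: int = 50_000, n_taxa: int = 120) -> CohortDesign:
    """A tissue-only design (7 days x 6 replicates = 42 samples)."""
    return CohortDesign(
        sample_types=("tissue",),
        n_bacterial_taxa=n_taxa,
        n_fungal_taxa=0,
        read_depth=read_depth,
        seed=seed,
    )
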