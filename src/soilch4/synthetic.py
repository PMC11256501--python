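"""Synthetic inputs for the full microcosm analysis chain.

Generates every file the pipeline consumes — chamber concentration series,
end-of-experiment isotope samples, amplicon count tables and qPCR Cq tables —
for a 3 sites × 2 temperatures × 2 flooding × 4 replicates factorial design
sampled on nine days over a 30-day incubation.

The chamber generator embeds a known flux through the same physical model the
estimator inverts (ideal-gas ppm→mass conversion, linear mass accrual) but
through its own arithmetic, so round-trip tests exercise two independent code
paths. Isotope sets follow exact conservative two-member mixing above an
atmospheric background. Count tables draw lognormal-abundance multinomials
with curated methanogen/methanotroph names and configurable
generalist/specialist structure. Cq tables follow the standard log-linear
amplification model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from soilch4.chamber import ChamberSeries
from soilch4.community import DEFAULT_GUILDS, CountTable, CuratedGuildList
from soilch4.isotopes import IsotopeSample

__all__ = [
    "ExperimentConfig",
    "ChamberTruth",
    "MixingTruth",
    "ExperimentBundle",
    "gen_chamber_series",
    "gen_keeling_set",
    "gen_count_table",
    "gen_qpcr_standards",
    "gen_experiment",
]

# physical constants, written out here rather than imported so that the
# generator's ppm<->mass arithmetic stays independent of the estimator's
_R = 0.082  # L·atm·mol⁻¹·K⁻¹
_MM_CH4 = 16.043  # g/mol
_MM_C = 12.011  # g/mol


class ConfigurationError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    """Factorial design and jar physics for the simulated incubation.

    Defaults mirror a two-floodplain + one-upland-forest design: 1.5-L jars
    with 400 g fresh soil at 30 % gravimetric moisture (280 g dry soil),
    10-s analyzer cadence over 600 s, sampling on days 0–30.
    """

    sites: tuple[str, ...] = ("FP1", "FP2", "PFO")
    temperatures: tuple[float, ...] = (27.0, 30.0)
    flooding: tuple[str, ...] = ("wet", "dry")
    replicates: int = 4
    days: tuple[int, ...] = (0, 1, 3, 6, 9, 13, 17, 23, 30)
    jar_volume_L: float = 1.5
    fresh_soil_g: float = 400.0
    moisture_fraction: float = 0.30
    soil_dry_mass_g: float | None = None  # derived from fresh mass if None
    pressure_atm: float = 1.0
    cadence_s: float = 10.0
    duration_s: float = 600.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence_s <= 0 or self.duration_s <= 0:
            raise ConfigurationError("cadence and duration must be positive")
        n = self.duration_s / self.cadence_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "duration must be an integer multiple of cadence"
            )
        if len(self.days) < 1 or self.days[0] != 0:
            raise ConfigurationError("days must start at 0")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ConfigurationError("days must be strictly increasing")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if not 0 <= self.moisture_fraction < 1:
            raise ConfigurationError("moisture_fraction must be in [0, 1)")

    @property
    def n_readings(self) -> int:
        return int(round(self.duration_s / self.cadence_s))

    @property
    def dry_mass_g(self) -> float:
        if self.soil_dry_mass_g is not None:
            return self.soil_dry_mass_g
        return self.fresh_soil_g * (1.0 - self.moisture_fraction)

    def jars(self) -> list[dict]:
        """All site × temperature × flooding × replicate jar records."""
        out = []
        for site, temp, flood, rep in itertools.product(
            self.sites, self.temperatures, self.flooding,
            range(1, self.replicates + 1),
        ):
            out.append(
                {
                    "jar_id": f"{site}-{int(temp)}C-{flood}-r{rep}",
                    "site": site,
                    "temperature": temp,
                    "flooding": flood,
                    "replicate": rep,
                    "volume_L": self.jar_volume_L,
                    "pressure_atm": self.pressure_atm,
                    "temp_K": 273.15 + temp,
                    "soil_dry_mass_g": self.dry_mass_g,
                }
            )
        return out


@dataclass(frozen=True)
class ChamberTruth:
    """Ground truth for one simulated chamber series.

    ``true_flux`` is in µg C–CH4 g dw⁻¹ h⁻¹ (negative = consumption). The
    closed-loop stabilization transient is a single exponential decay with
    default timescale 30 s, negligible after the 100-s trim window.
    """

    true_flux: float
    transient_amplitude: float = 0.3
    transient_timescale_s: float = 30.0
    noise_sd_ppm: float = 0.0
    baseline_ppm: float = 1.9

    def __post_init__(self) -> None:
        if self.transient_timescale_s <= 0:
            raise ValueError("transient_timescale_s must be positive")
        if self.noise_sd_ppm < 0 or self.baseline_ppm < 0:
            raise ValueError("noise_sd_ppm and baseline_ppm must be >= 0")


@dataclass(frozen=True)
class MixingTruth:
    """Two-member isotope mixing scenario: soil source above atmosphere."""

    source_d13C: float  # ‰ vs VPDB
    source_d2H: float  # ‰ vs VSMOW
    background_ppm: float = 1.9
    background_d13C: float = -47.0
    background_d2H: float = -90.0
    added_ppm_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    noise_sd_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.background_ppm <= 0:
            raise ValueError("background_ppm must be positive")
        totals = {self.background_ppm + a for a in self.added_ppm_levels}
        totals.add(self.background_ppm)
        if len(totals) < 3:
            raise DegenerateDesignError(
                "need at least 3 distinct total concentrations"
            )


def gen_chamber_series(
    config: ExperimentConfig,
    truth: ChamberTruth,
    jar_metadata: dict,
    rng: np.random.Generator | None = None,
) -> ChamberSeries:
    """Simulate one jar's headspace concentration time course.

    Expected ppm at time t:
    ``baseline + amplitude·exp(−t/τ) + slope_ppm·t`` where ``slope_ppm`` is
    the ppm-per-second rate implied by ``true_flux`` under the ideal gas law
    for this jar's volume, pressure and temperature. Gaussian noise with sd
    ``noise_sd_ppm`` is added independently per reading.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_readings
    t = config.cadence_s * np.arange(1, n + 1)

    p = jar_metadata["pressure_atm"]
    v = jar_metadata["volume_L"]
    tk = jar_metadata["temp_K"]
    dw = jar_metadata["soil_dry_mass_g"]
    # µg C/h → µg CH4/s → ppm/s (headspace holds P·V/(R·T) mol)
    slope_ug_ch4_per_s = truth.true_flux * dw / (_MM_C / _MM_CH4) / 3600.0
    slope_ppm_per_s = slope_ug_ch4_per_s * (_R * tk) / (_MM_CH4 * p * v)

    expected = (
        truth.baseline_ppm
        + truth.transient_amplitude * np.exp(-t / truth.transient_timescale_s)
        + slope_ppm_per_s * t
    )
    noise = rng.normal(0.0, truth.noise_sd_ppm, size=n) if truth.noise_sd_ppm > 0 else 0.0
    return ChamberSeries(
        jar_id=jar_metadata.get("jar_id", "jar"),
        times=t,
        ch4_ppm=expected + noise,
        pressure_atm=p,
        volume_L=v,
        temp_K=tk,
        soil_dry_mass_g=dw,
        site=jar_metadata.get("site", ""),
        temperature_level=jar_metadata.get("temperature", float("nan")),
        flooding_level=jar_metadata.get("flooding", ""),
        replicate=jar_metadata.get("replicate", 0),
        day=jar_metadata.get("day", 0),
    )


def gen_keeling_set(
    truth: MixingTruth,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "s",
) -> list[IsotopeSample]:
    """Exact two-member mixing samples plus one atmospheric background.

    Each sample mixes ``added`` ppm of source CH4 into ``background_ppm`` of
    atmosphere; conservation of each isotopologue gives
    ``δ_mix = (C_bg·δ_bg + C_add·δ_src)/C_tot`` per isotope system. Optional
    Gaussian noise perturbs the δ values only.
    """
    if all(a == 0 for a in truth.added_ppm_levels):
        raise DegenerateDesignError("all added CH4 levels are zero")
    if rng is None:
        rng = np.random.default_rng(0)
    samples = []
    for i, added in enumerate(truth.added_ppm_levels):
        c_tot = truth.background_ppm + added
        d13 = (
            truth.background_ppm * truth.background_d13C + added * truth.source_d13C
        ) / c_tot
        d2 = (
            truth.background_ppm * truth.background_d2H + added * truth.source_d2H
        ) / c_tot
        if truth.noise_sd_delta > 0:
            d13 += rng.normal(0.0, truth.noise_sd_delta)
            d2 += rng.normal(0.0, truth.noise_sd_delta)
        samples.append(
            IsotopeSample(
                ch4_ppm=c_tot, d13C=d13, d2H=d2,
                sample_id=f"{sample_prefix}{i}",
            )
        )
    samples.append(
        IsotopeSample(
            ch4_ppm=truth.background_ppm,
            d13C=truth.background_d13C,
            d2H=truth.background_d2H,
            is_background=True,
            sample_id=f"{sample_prefix}-bg",
        )
    )
    return samples


_RANKS = ("d", "p", "c", "o", "f", "g")


def _lineage(genus: str, i: int) -> str:
    return (
        f"d__Domain{i % 2};p__Phylum{i % 7};c__Class{i % 11};"
        f"o__Order{i % 13};f__Family{i % 17};g__{genus}"
    )


def gen_count_table(
    n_samples: int = 16,
    n_taxa: int = 200,
    guild_fraction: float = 0.05,
    specialist_structure: tuple[int, int] = (5, 5),
    mean_depth: int = 40_000,
    depth_cv: float = 0.15,
    specialist_fold: float = 8.0,
    guild_mean_abundance: float = 0.025,
    group_labels: tuple[str, str] = ("A", "B"),
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
) -> CountTable:
    """Sample × taxon counts with guild and generalist/specialist structure.

    Taxon relative abundances are lognormal; per-sample counts are
    multinomial at a lognormal depth (CV ``depth_cv`` around ``mean_depth``).
    ``guild_fraction`` of taxa carry curated methanogen/methanotroph genus
    names (split evenly) and jointly hold ``guild_mean_abundance`` of the
    community. ``specialist_structure = (nA, nB)`` taxa are enriched
    ``specialist_fold``-fold in group A or B respectively; the remaining taxa
    are uniform across groups (generalists). Sample groups alternate A/B
    unless ``metadata`` provides a ``group`` column.
    """
    if not 0 <= guild_fraction <= 1:
        raise ValueError("guild_fraction must be in [0, 1]")
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    rng = np.random.default_rng(seed)

    n_guild = int(round(guild_fraction * n_taxa))
    # interleave so both guilds are represented even at small guild counts
    guild_names = [
        name
        for pair in itertools.zip_longest(
            DEFAULT_GUILDS.methanogens, DEFAULT_GUILDS.methanotrophs
        )
        for name in pair
        if name is not None
    ]
    taxa, lineages, guild_flags = [], [], []
    for i in range(n_taxa):
        if i < n_guild:
            genus = guild_names[i % len(guild_names)].replace(" ", "_")
            name = f"t{i:04d}_{genus}"
        else:
            genus = f"Taxon{i:04d}"
            name = f"t{i:04d}"
        taxa.append(name)
        lineages.append(_lineage(genus, i))
        guild_flags.append(i < n_guild)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
    base = base / base.sum()
    flags = np.asarray(guild_flags)
    if n_guild > 0:
        # rescale so guild taxa jointly hold guild_mean_abundance
        base[flags] *= guild_mean_abundance / base[flags].sum()
        base[~flags] *= (1.0 - guild_mean_abundance) / base[~flags].sum()

    n_a, n_b = specialist_structure
    nonguild = np.flatnonzero(~flags)
    if n_a + n_b > nonguild.size:
        raise ValueError("more specialists requested than non-guild taxa")
    spec_a = nonguild[:n_a]
    spec_b = nonguild[n_a : n_a + n_b]

    p_by_group = {}
    for label, up, down in (
        (group_labels[0], spec_a, spec_b),
        (group_labels[1], spec_b, spec_a),
    ):
        p = base.copy()
        p[up] *= specialist_fold
        p[down] /= specialist_fold
        p_by_group[label] = p / p.sum()

    if metadata is not None and "group" in metadata.columns:
        groups = metadata["group"].tolist()
        sample_ids = metadata.index.tolist()
    else:
        groups = [group_labels[i % 2] for i in range(n_samples)]
        sample_ids = [f"sample{i:03d}" for i in range(n_samples)]

    sigma = np.sqrt(np.log1p(depth_cv**2))
    depths = rng.lognormal(np.log(mean_depth) - sigma**2 / 2, sigma, size=n_samples)
    counts = np.vstack(
        [
            rng.multinomial(int(round(depths[i])), p_by_group[groups[i]])
            for i in range(n_samples)
        ]
    )
    meta = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample"))
    if metadata is not None:
        meta = metadata.copy()
    return CountTable(
        counts=pd.DataFrame(counts, index=meta.index, columns=taxa),
        taxonomy=pd.Series(lineages, index=taxa, name="taxonomy"),
        metadata=meta,
    )


def gen_qpcr_standards(
    true_slope: float = -3.3219,
    true_intercept: float = 36.0,
    noise_sd_cq: float = 0.0,
    levels: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6),
    gene: str = "mcrA",
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Dilution-series standards: ``Cq = intercept + slope·log10(copies) + ε``.

    Default levels span 10⁰–10⁶ copies; slope −3.3219 corresponds to perfect
    per-cycle doubling (100 % efficiency).
    """
    if len(levels) < 3:
        raise DegenerateDesignError("a standard curve needs at least 3 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for lvl in levels:
        for rep in range(1, replicates + 1):
            cq = true_intercept + true_slope * lvl
            if noise_sd_cq > 0:
                cq += rng.normal(0.0, noise_sd_cq)
            rows.append(
                {
                    "gene": gene,
                    "role": "standard",
                    "sample_id": f"std-1e{lvl}",
                    "log10_copies": float(lvl),
                    "cq": cq,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def _treatment_flux(site: str, temp: float, flood: str, day: int) -> float:
    """Deterministic treatment-level true flux (µg C g dw⁻¹ h⁻¹).

    Flooded treatments emit, ramping up quadratically over the incubation and
    boosted by warming, anchored so the upland-forest wet/+3 °C jar reaches
    5e−3 µg C g⁻¹ h⁻¹ on day 30; dry treatments consume CH4 at a low steady
    rate that warming attenuates by ~60 %.
    """
    warm = (temp - 27.0) / 3.0  # 0 at control, 1 at +3 °C
    if flood == "wet":
        site_scale = {"FP1": 0.5, "FP2": 0.3, "PFO": 1.0}.get(site, 1.0)
        ramp = (day / 30.0) ** 2
        return site_scale * (0.4 + 0.6 * warm) * 5e-3 * ramp + 1e-4
    site_scale = {"FP1": 1.0, "FP2": 1.2, "PFO": 1.5}.get(site, 1.0)
    return -site_scale * (1.0 - 0.6 * warm) * 2e-4


@dataclass(frozen=True)
class ExperimentBundle:
    """Everything the analysis chain consumes, indexed by jar and day."""

    config: ExperimentConfig
    chamber_series: dict  # (jar_id, day) -> ChamberSeries
    true_fluxes: dict  # (jar_id, day) -> µg C g dw⁻¹ h⁻¹
    isotope_samples: list  # day-30 IsotopeSample set incl. background
    count_tables: dict  # day -> CountTable (days 0 and 30 only)
    qpcr: pd.DataFrame  # standards + unknowns, long format

    def chamber_frame(self) -> pd.DataFrame:
        """Long-format CSV-ready frame of every chamber reading."""
        rows = []
        for (jar, day), s in self.chamber_series.items():
            rows.append(
                pd.DataFrame(
                    {
                        "jar_id": jar,
                        "site": s.site,
                        "temperature": s.temperature_level,
                        "flooding": s.flooding_level,
                        "replicate": s.replicate,
                        "day": day,
                        "time_s": s.times,
                        "ch4_ppm": s.ch4_ppm,
                        "pressure_atm": s.pressure_atm,
                        "volume_L": s.volume_L,
                        "temp_K": s.temp_K,
                        "soil_dry_mass_g": s.soil_dry_mass_g,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def isotope_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.isotope_samples],
                "treatment": [s.treatment for s in self.isotope_samples],
                "ch4_ppm": [s.ch4_ppm for s in self.isotope_samples],
                "d13C": [s.d13C for s in self.isotope_samples],
                "d2H": [s.d2H for s in self.isotope_samples],
                "is_background": [s.is_background for s in self.isotope_samples],
            }
        )


def gen_experiment(
    config: ExperimentConfig | None = None,
    chamber_noise_sd_ppm: float = 0.001,
    flux_replicate_cv: float = 0.15,
    isotope_noise_sd: float = 1.0,
    count_kwargs: dict | None = None,
    qpcr_noise_sd_cq: float = 0.1,
) -> ExperimentBundle:
    """Simulate the whole incubation, deterministically under the config seed.

    Chamber series for every jar on every sampling day; one Keeling isotope
    set per treatment on day 30 (source δ depends on flooding: wet jars emit
    production-signature CH4, dry jars an oxidation-enriched residue); count
    tables for days 0 and 30 with flooding as the A/B grouping; standards and
    unknown Cq values for the four assayed genes.
    """
    if config is None:
        config = ExperimentConfig()
    rng = np.random.default_rng(config.rng_seed)
    jars = config.jars()

    series: dict = {}
    truths: dict = {}
    for jar in jars:
        jitter = rng.normal(1.0, flux_replicate_cv)
        for day in config.days:
            f = _treatment_flux(jar["site"], jar["temperature"], jar["flooding"], day)
            f *= jitter
            truth = ChamberTruth(
                true_flux=f, noise_sd_ppm=chamber_noise_sd_ppm,
                baseline_ppm=1.9 + max(0.0, f) * day * 5.0,
            )
            md = dict(jar, day=day)
            series[(jar["jar_id"], day)] = gen_chamber_series(config, truth, md, rng)
            truths[(jar["jar_id"], day)] = f

    iso_samples: list[IsotopeSample] = []
    bg_added = False
    for site, temp, flood in itertools.product(
        config.sites, config.temperatures, config.flooding
    ):
        label = f"{site}-{int(temp)}C-{flood}"
        if flood == "wet":
            src13 = rng.uniform(-75.0, -55.0)
            src2 = rng.uniform(-330.0, -200.0)
            added = (1.0, 2.0, 4.0, 8.0)
        else:
            src13 = rng.uniform(-45.0, -30.0)
            src2 = rng.uniform(-120.0, -40.0)
            added = (0.3, 0.6, 1.2, 2.4)
        truth = MixingTruth(
            source_d13C=src13, source_d2H=src2,
            added_ppm_levels=added, noise_sd_delta=isotope_noise_sd,
        )
        batch = gen_keeling_set(truth, rng, sample_prefix=f"{label}-")
        for s in batch:
            if s.is_background:
                if bg_added:
                    continue
                bg_added = True
                iso_samples.append(replace(s, sample_id="atmosphere"))
            else:
                iso_samples.append(replace(s, treatment=label))

    ck = dict(
        n_samples=len(jars), n_taxa=200, guild_fraction=0.08,
        specialist_structure=(8, 8), mean_depth=40_000,
    )
    ck.update(count_kwargs or {})
    tables = {}
    for day in (0, 30):
        meta = pd.DataFrame(
            {
                "site": [j["site"] for j in jars],
                "temperature": [j["temperature"] for j in jars],
                "flooding": [j["flooding"] for j in jars],
                "replicate": [j["replicate"] for j in jars],
                "day": day,
                "group": [j["flooding"] for j in jars],
            },
            index=pd.Index([j["jar_id"] for j in jars], name="sample"),
        )
        tables[day] = gen_count_table(
            metadata=meta, group_labels=("wet", "dry"),
            seed=int(rng.integers(2**31)), **ck,
        )

    genes = {
        "16S-archaea": (-3.40, 38.0, 8.0),
        "16S-bacteria": (-3.35, 37.0, 9.5),
        "mcrA": (-3.45, 37.5, 6.5),
        "pmoA": (-3.30, 36.5, 6.0),
    }
    qpcr_frames = []
    for gene, (slope, icept, log10_mean) in genes.items():
        qpcr_frames.append(
            gen_qpcr_standards(
                true_slope=slope, true_intercept=icept,
                noise_sd_cq=qpcr_noise_sd_cq, gene=gene,
                seed=int(rng.integers(2**31)),
            )
        )
        rows = []
        for jar in jars:
            for day in (0, 30):
                log10_copies = rng.normal(log10_mean, 0.4)
                for rep in (1, 2, 3):
                    cq = icept + slope * log10_copies
                    cq += rng.normal(0.0, qpcr_noise_sd_cq)
                    rows.append(
                        {
                            "gene": gene, "role": "unknown",
                            "sample_id": f"{jar['jar_id']}-d{day}",
                            "log10_copies": float("nan"),
                            "cq": cq, "replicate": rep,
                        }
                    )
        qpcr_frames.append(pd.DataFrame(rows))

    return ExperimentBundle(
        config=config,
        chamber_series=series,
        true_fluxes=truths,
        isotope_samples=iso_samples,
        count_tables=tables,
        qpcr=pd.concat(qpcr_frames, ignore_index=True),
    )


def write_bundle(bundle: ExperimentBundle, outdir) -> None:
    """Write the bundle as the CSV/TSV files the analysis CLI reads."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.chamber_frame().to_csv(out / "chamber_series.csv", index=False)
    bundle.isotope_frame().to_csv(out / "isotope_samples.csv", index=False)
    bundle.qpcr.to_csv(out / "qpcr.csv", index=False)
    for day, table in bundle.count_tables.items():
        table.to_tsv(out / f"counts_day{day}.tsv")
        table.metadata.to_csv(out / f"sample_metadata_day{day}.csv")
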