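"""Synthetic screen generator with a ground-truth record.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale, so every downstream stage is testable without
external data:

* a 384-well layout with diagonally placed controls and horizontal 7-point
  2-fold dilution series, compounds split across two plate positions, three
  replicates;
* per-cell feature values drawn from Gaussian, log-normal or bimodal-mixture
  control distributions (the bimodal mixture models total-DNA content with
  2n/4n cell-cycle peaks);
* dose-dependent treatment effects under a Hill response (location shift,
  scale change, tail stretch, G1:G2 weight shift), acting on the latent
  value before technical artifacts are overlaid;
* additive row/column positional artifacts (linear-in-index), concentrated
  on intensity features, with a per-plate random magnitude;
* per-plate additive offsets and multiplicative scale factors per feature;
* over-dispersed (truncated negative-binomial) cell counts per well, with
  cytotoxicity multiplying the count scale.

Because positional artifacts are strictly additive in row and column they
are exactly removable by an ideal additive decomposition, which is what the
closed-loop tests of the QC/normalization stages rely on.  Identical seed
and configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import CONTROL_ID, META_COLUMNS, FeatureCatalog, PlateLayout, build_default_layout

__all__ = [
    "Gaussian", "LogNormal", "BimodalMixture",
    "FeatureSpec", "Effect", "TreatmentSpec", "PositionalSpec", "PlateEffectSpec",
    "CountSpec", "SimulationConfig", "GroundTruth",
    "simulate_screen", "sample_dna_content",
    "default_config", "null_config", "full_config",
    "paper_count_spec", "default_features", "default_catalog",
]


# ---------------------------------------------------------------------------
# Control distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gaussian:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size=n)

    def median(self) -> float:
        return self.mu

    def mad(self) -> float:
        return self.sigma * stats.norm.ppf(0.75)

    def cdf(self, x):
        return stats.norm.cdf(x, self.mu, self.sigma)


@dataclass(frozen=True)
class LogNormal:
    """log X ~ N(mu, sigma); right-skewed, heavy upper tail."""
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)

    def median(self) -> float:
        return float(np.exp(self.mu))

    def cdf(self, x):
        return stats.lognorm.cdf(x, s=self.sigma, scale=np.exp(self.mu))

    def mad(self) -> float:
        return _numeric_mad(self.cdf, self.median())


@dataclass(frozen=True)
class BimodalMixture:
    """Two-component Gaussian mixture; models 2n/4n DNA-content peaks."""
    mu1: float
    mu2: float
    sigma: float
    weight: float  # mass on mode 1 (G1 / 2n)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.weight < 1):
            raise ValueError("bimodal weight must lie in (0, 1)")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.random(n) < self.weight
        x = rng.normal(self.mu2, self.sigma, size=n)
        x[pick] = rng.normal(self.mu1, self.sigma, size=int(pick.sum()))
        return x

    def cdf(self, x):
        return (self.weight * stats.norm.cdf(x, self.mu1, self.sigma)
                + (1 - self.weight) * stats.norm.cdf(x, self.mu2, self.sigma))

    def median(self) -> float:
        lo = min(self.mu1, self.mu2) - 6 * self.sigma
        hi = max(self.mu1, self.mu2) + 6 * self.sigma
        return float(optimize.brentq(lambda x: self.cdf(x) - 0.5, lo, hi))

    def mad(self) -> float:
        return _numeric_mad(self.cdf, self.median())


def _numeric_mad(cdf, median: float) -> float:
    """Root-find the MAD from a CDF: P(|X - m| <= q) = 1/2."""
    f = lambda q: cdf(median + q) - cdf(median - q) - 0.5
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
    return float(optimize.brentq(f, 1e-12, hi))


def sample_dna_content(n: int, g1_weight: float, spec: "FeatureSpec",
                       rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` DNA-content values with the given G1-mode mass.

    The feature's control distribution must be a :class:`BimodalMixture`;
    ``g1_weight`` overrides the mass on the 2n mode.  ``g1_weight = 1`` is
    the degenerate all-G1 population (unimodal at the 2n mode).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0 < g1_weight <= 1):
        raise ValueError("g1_weight must lie in (0, 1]")
    dist = spec.distribution
    if not isinstance(dist, BimodalMixture):
        raise TypeError("sample_dna_content requires a bimodal feature")
    if g1_weight == 1.0:
        return rng.normal(dist.mu1, dist.sigma, size=n)
    return replace(dist, weight=g1_weight).sample(n, rng)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    feature_class: str            # intensity | shape | texture | spot
    distribution: Gaussian | LogNormal | BimodalMixture
    marker: str = "generic"
    compartment: str = "Circ"     # Circ (nucleus) | Ring (cytoplasm)
    well_jitter: float = 0.0      # extra per-well random offset, in latent-MAD units


@dataclass(frozen=True)
class Effect:
    """Per-feature treatment effect at the top dose (attenuated by the Hill
    fraction at lower doses)."""
    shift: float = 0.0        # additive location shift, raw feature units
    scale: float = 1.0        # multiplicative spread change about the median
    tail: float = 0.0         # stretch exponent applied to positive residuals
    g1_shift: float = 0.0     # additive change of the bimodal G1 weight

    @property
    def pure_shift(self) -> bool:
        return self.scale == 1.0 and self.tail == 0.0 and self.g1_shift == 0.0


@dataclass(frozen=True)
class TreatmentSpec:
    compound: str
    effects: dict[str, Effect] = field(default_factory=dict)
    hill: float = 2.0        # Hill exponent of the dose response
    ec50: float = 1.25       # uM
    toxicity: float = 0.0    # max fractional cell-count reduction at full effect

    def hill_fraction(self, conc: float) -> float:
        """Effect strength in [0, 1); monotone non-decreasing in dose."""
        c = conc ** self.hill
        return c / (c + self.ec50 ** self.hill)

    def count_fraction(self, conc: float) -> float:
        return 1.0 - self.toxicity * self.hill_fraction(conc)


@dataclass(frozen=True)
class PositionalSpec:
    """Additive row/column artifact amplitudes per feature class.

    Amplitudes are expressed in units of each feature's latent MAD; the
    realized per-plate artifact is a linear-in-index vector spanning
    [-amp, +amp] times a per-plate random magnitude factor.  The default puts
    markedly larger artifacts on intensity features than on morphology.
    """
    amplitudes: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "intensity": (1.2, 0.6),
        "shape": (0.1, 0.05),
        "texture": (0.1, 0.05),
        "spot": (0.1, 0.05),
    })
    plate_magnitude_range: tuple[float, float] = (0.6, 1.4)

    def for_class(self, feature_class: str) -> tuple[float, float]:
        return self.amplitudes.get(feature_class, (0.0, 0.0))


@dataclass(frozen=True)
class PlateEffectSpec:
    """Per-(plate, feature) additive offset and multiplicative scale."""
    offset_sd: float = 0.5    # in latent-MAD units
    scale_sd: float = 0.08    # scale factor ~ 1 + N(0, scale_sd)


@dataclass(frozen=True)
class CountSpec:
    """Truncated negative-binomial cells-per-well sampler.

    Over-dispersed counts with hard truncation to [lo, hi]; cytotoxicity
    multiplies mean and bounds by the surviving fraction.
    """
    mean: float = 650.0
    dispersion: float = 50.0  # NB size parameter; larger = closer to Poisson
    lo: int = 419
    hi: int = 990

    def sample(self, rng: np.random.Generator, fraction: float = 1.0) -> int:
        mu = self.mean * fraction
        if mu <= 0:
            return 0
        p = self.dispersion / (self.dispersion + mu)
        n = int(rng.negative_binomial(self.dispersion, p))
        lo = int(round(self.lo * fraction))
        hi = max(lo, int(round(self.hi * fraction)))
        return int(np.clip(n, lo, hi))


def paper_count_spec() -> CountSpec:
    """Control cells-per-well sampler calibrated to the published control
    range (min 419, max 990 cells per well)."""
    return CountSpec(mean=650.0, dispersion=50.0, lo=419, hi=990)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_replicates: int = 3
    plates_per_replicate: int = 2
    features: tuple[FeatureSpec, ...] = ()
    treatments: tuple[TreatmentSpec, ...] = ()
    positional: PositionalSpec = field(default_factory=PositionalSpec)
    plate_effect: PlateEffectSpec = field(default_factory=PlateEffectSpec)
    counts: CountSpec = field(default_factory=paper_count_spec)
    top_conc: float = 10.0
    n_doses: int = 7

    def layouts(self) -> list[PlateLayout]:
        """One layout per plate position; compounds split across positions."""
        compounds = [t.compound for t in self.treatments]
        n_pos = self.plates_per_replicate
        per_pos = [compounds[i::n_pos] for i in range(n_pos)]
        return [build_default_layout(cpds or 1, top_conc=self.top_conc,
                                     n_doses=self.n_doses)
                for cpds in per_pos]

    def catalog(self) -> FeatureCatalog:
        return FeatureCatalog.from_records([
            {"feature": f.name, "marker": f.marker, "compartment": f.compartment,
             "feature_class": f.feature_class}
            for f in self.features
        ])


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator injected, for closed-loop testing.

    ``row_effects``/``col_effects``: realized additive artifact vectors per
    (plate, replicate, feature), indexed over inner rows/columns.
    ``condition_effects``: per (compound, concentration, feature) the Hill
    fraction, the injected effect parameters, and ``expected_bz_shift`` =
    |shift| x Hill fraction / latent MAD — for pure location shifts this is
    the expected EMD of the condition against the control in BZ units.
    ``count_fractions``: expected surviving cell-count fraction per condition.
    """

    latent_median: dict[str, float]
    latent_mad: dict[str, float]
    row_effects: dict[tuple[str, int, str], np.ndarray]
    col_effects: dict[tuple[str, int, str], np.ndarray]
    plate_offset: dict[tuple[str, int, str], float]
    plate_scale: dict[tuple[str, int, str], float]
    condition_effects: pd.DataFrame
    count_fractions: pd.DataFrame

    def toxic_conditions(self, threshold: float = 0.30) -> set[tuple[str, float]]:
        """Conditions whose expected count fraction falls below ``threshold``
        (i.e. more than 1 - threshold cell reduction)."""
        sub = self.count_fractions[self.count_fractions["fraction"] < threshold]
        return {(r.compound, r.concentration) for r in sub.itertuples()}

    def positionally_affected(self, min_amplitude: float = 0.5) -> set[str]:
        """Features whose injected artifact amplitude (in MAD units) is large."""
        out = set()
        for (_, _, feat), vec in self.row_effects.items():
            if np.ptp(vec) / (2 * self.latent_mad[feat]) >= min_amplitude:
                out.add(feat)
        return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _apply_effect(latent: np.ndarray, spec: FeatureSpec, eff: Effect,
                  h: float, med: float, scale_unit: float) -> np.ndarray:
    x = latent
    s = 1.0 + (eff.scale - 1.0) * h
    if s != 1.0:
        x = med + s * (x - med)
    if eff.tail != 0.0 and h > 0:
        r = x - med
        pos = r > 0
        r_pos = r[pos] / scale_unit
        r[pos] = np.power(r_pos, 1.0 + eff.tail * h) * scale_unit
        x = med + r
    if eff.shift != 0.0:
        x = x + eff.shift * h
    return x


def _sample_latent(spec: FeatureSpec, eff: Effect | None, h: float,
                   n: int, rng: np.random.Generator,
                   med: float, unit: float) -> np.ndarray:
    dist = spec.distribution
    if eff is not None and eff.g1_shift != 0.0 and isinstance(dist, BimodalMixture):
        w = float(np.clip(dist.weight + eff.g1_shift * h, 0.01, 0.99))
        dist = replace(dist, weight=w)
    latent = dist.sample(n, rng)
    if eff is not None:
        latent = _apply_effect(latent, spec, eff, h, med, unit)
    return latent


def simulate_screen(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full synthetic screen and its ground-truth record.

    Returns the long-format cell table (all replicates, plate positions and
    inner wells) and a :class:`GroundTruth`.  Deterministic given
    ``config.seed``.
    """
    if not config.features:
        raise ValueError("simulation config declares no features")
    rng = np.random.default_rng(config.seed)
    layouts = config.layouts()
    treatments = {t.compound: t for t in config.treatments}

    latent_median = {f.name: f.distribution.median() for f in config.features}
    latent_mad = {f.name: f.distribution.mad() for f in config.features}

    row_fx: dict = {}
    col_fx: dict = {}
    p_off: dict = {}
    p_scl: dict = {}
    blocks: list[dict] = []

    for rep in range(1, config.n_replicates + 1):
        for pos, layout in enumerate(layouts, start=1):
            plate = f"plate{pos}"
            n_ir = len(layout.inner_row_range())
            n_ic = len(layout.inner_col_range())
            row_lin = np.linspace(-1.0, 1.0, n_ir)
            col_lin = np.linspace(-1.0, 1.0, n_ic)
            # realized per-plate artifact and plate-effect parameters
            for f in config.features:
                amp_r, amp_c = config.positional.for_class(f.feature_class)
                lo, hi = config.positional.plate_magnitude_range
                mag = rng.uniform(lo, hi)
                unit = latent_mad[f.name]
                key = (plate, rep, f.name)
                row_fx[key] = amp_r * mag * unit * row_lin
                col_fx[key] = amp_c * mag * unit * col_lin
                p_off[key] = rng.normal(0.0, config.plate_effect.offset_sd * unit)
                p_scl[key] = max(0.2, 1.0 + rng.normal(0.0, config.plate_effect.scale_sd))

            r0 = layout.inner_rows[0]
            c0 = layout.inner_cols[0]
            for (r, c) in layout.inner_wells():
                role = layout.well_role(r, c)
                if role == "empty":
                    continue
                if role == "control":
                    cpd, conc, h, frac = CONTROL_ID, np.nan, 0.0, 1.0
                    eff_map: dict[str, Effect] = {}
                else:
                    cpd, conc, _ = layout.treatment_map[(r, c)]
                    t = treatments[cpd]
                    h = t.hill_fraction(conc)
                    frac = t.count_fraction(conc)
                    eff_map = t.effects
                n = config.counts.sample(rng, frac)
                if n == 0:
                    continue
                block = {
                    "plate": plate, "replicate": rep, "row": r, "col": c,
                    "treatment": cpd, "concentration": conc, "_n": n,
                }
                for f in config.features:
                    key = (plate, rep, f.name)
                    unit = latent_mad[f.name]
                    latent = _sample_latent(f, eff_map.get(f.name), h, n, rng,
                                            latent_median[f.name], unit)
                    vals = p_scl[key] * latent + p_off[key]
                    vals = vals + row_fx[key][r - r0] + col_fx[key][c - c0]
                    if f.well_jitter:
                        vals = vals + rng.normal(0.0, f.well_jitter * unit)
                    block[f.name] = vals
                blocks.append(block)

    frames = []
    feat_names = [f.name for f in config.features]
    for b in blocks:
        n = b.pop("_n")
        d = {k: np.repeat(b[k], n) for k in ("plate", "replicate", "row", "col",
                                             "treatment", "concentration")}
        for fn in feat_names:
            d[fn] = b[fn]
        frames.append(pd.DataFrame(d))
    cells = pd.concat(frames, ignore_index=True)[META_COLUMNS + feat_names]

    # ground-truth condition table
    cond_rows, count_rows = [], []
    seen = set()
    for layout in layouts:
        for (cpd, conc, idx) in layout.treatment_map.values():
            if (cpd, conc) in seen:
                continue
            seen.add((cpd, conc))
            t = treatments[cpd]
            h = t.hill_fraction(conc)
            count_rows.append({"compound": cpd, "concentration": conc,
                               "dose_index": idx, "fraction": t.count_fraction(conc)})
            for f in config.features:
                eff = t.effects.get(f.name, Effect())
                cond_rows.append({
                    "compound": cpd, "concentration": conc, "dose_index": idx,
                    "feature": f.name, "hill_fraction": h,
                    "shift": eff.shift, "scale": eff.scale, "tail": eff.tail,
                    "g1_shift": eff.g1_shift, "pure_shift": eff.pure_shift,
                    "expected_bz_shift": abs(eff.shift) * h / latent_mad[f.name],
                })
    truth = GroundTruth(
        latent_median=latent_median, latent_mad=latent_mad,
        row_effects=row_fx, col_effects=col_fx,
        plate_offset=p_off, plate_scale=p_scl,
        condition_effects=pd.DataFrame.from_records(cond_rows),
        count_fractions=pd.DataFrame.from_records(count_rows),
    )
    return cells, truth


def design_summary(config: SimulationConfig) -> dict:
    """Bookkeeping of a screen design without simulating it.

    Counts the analyzable wells, the control samples (control wells x plate
    positions x replicates — controls are profiled per individual well) and
    the distinct treatment conditions (compound x concentration, replicates
    merged).
    """
    layouts = config.layouts()
    conditions = {(cpd, conc)
                  for layout in layouts
                  for (cpd, conc, _) in layout.treatment_map.values()}
    return {
        "inner_wells_per_plate": layouts[0].n_inner,
        "control_wells_per_plate": len(layouts[0].control_wells),
        "n_control_samples": sum(len(l.control_wells) for l in layouts) * config.n_replicates,
        "n_treatment_conditions": len(conditions),
    }


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

def default_features() -> tuple[FeatureSpec, ...]:
    """Desk-scale feature menu: 14 features across 4 classes and 8 markers,
    including a bimodal DNA-content feature, two heavy-tailed spot counts,
    two biologically irrelevant compartment/marker combinations and one
    feature with planted well-level jitter (poor reproducibility)."""
    return (
        FeatureSpec("DNA_TotalIntensity_Circ", "intensity",
                    BimodalMixture(1.0, 2.0, 0.15, 0.6), "DNA", "Circ"),
        FeatureSpec("DNA_AvgIntensity_Ring", "intensity",
                    Gaussian(0.8, 0.2), "DNA", "Ring"),
        FeatureSpec("RNA_AvgIntensity_Ring", "intensity",
                    LogNormal(0.0, 0.5), "RNA", "Ring"),
        FeatureSpec("Mito_TotalIntensity_Ring", "intensity",
                    Gaussian(5.0, 1.0), "mitochondria", "Ring"),
        FeatureSpec("PMG_AvgIntensity_Ring", "intensity",
                    Gaussian(3.0, 0.8), "PMG", "Ring"),
        FeatureSpec("Nuc_Area_Circ", "shape", Gaussian(10.0, 2.0), "DNA", "Circ"),
        FeatureSpec("Nuc_Elongation_Circ", "shape", Gaussian(1.5, 0.3), "DNA", "Circ"),
        FeatureSpec("Cell_Area_Ring", "shape", Gaussian(25.0, 5.0), "PMG", "Ring"),
        FeatureSpec("DNA_Texture_Entropy_Circ", "texture", Gaussian(2.0, 0.4), "DNA", "Circ"),
        FeatureSpec("Mito_Texture_Contrast_Ring", "texture",
                    Gaussian(1.0, 0.25), "mitochondria", "Ring"),
        FeatureSpec("RNA_Texture_Entropy_Ring", "texture",
                    Gaussian(2.5, 0.5), "RNA", "Ring", well_jitter=1.2),
        FeatureSpec("Lyso_Texture_Entropy_Circ", "texture",
                    Gaussian(1.8, 0.35), "lysosome", "Circ"),
        FeatureSpec("Lyso_SpotCount_Ring", "spot", LogNormal(2.0, 0.4), "lysosome", "Ring"),
        FeatureSpec("Peroxi_SpotCount_Ring", "spot", LogNormal(2.2, 0.35), "peroxisome", "Ring"),
    )


def default_catalog() -> FeatureCatalog:
    return default_config().catalog()


def _mad_of(features, name: str) -> float:
    for f in features:
        if f.name == name:
            return f.distribution.mad()
    raise KeyError(name)


def default_treatments(features=None) -> tuple[TreatmentSpec, ...]:
    """Eight planted compounds: two low-stress, three dose-responsive (pure
    location shifts of graded size), one dose-insensitive (low EC50, includes
    a Z-blind spread change), two cytotoxic.  Shifts are specified in units
    of each feature's latent MAD so that the expected BZ-scale effect is the
    stated multiple."""
    features = features or default_features()
    m = lambda name: _mad_of(features, name)
    return (
        TreatmentSpec("lowstress_1"),
        TreatmentSpec("lowstress_2"),
        TreatmentSpec("doseresp_1", effects={
            "Mito_TotalIntensity_Ring": Effect(shift=3.0 * m("Mito_TotalIntensity_Ring")),
            "Nuc_Area_Circ": Effect(shift=2.0 * m("Nuc_Area_Circ")),
            "DNA_Texture_Entropy_Circ": Effect(shift=1.0 * m("DNA_Texture_Entropy_Circ")),
        }, toxicity=0.25),
        TreatmentSpec("doseresp_2", effects={
            "PMG_AvgIntensity_Ring": Effect(shift=2.5 * m("PMG_AvgIntensity_Ring")),
            "Cell_Area_Ring": Effect(shift=1.5 * m("Cell_Area_Ring")),
            "Mito_Texture_Contrast_Ring": Effect(shift=0.8 * m("Mito_Texture_Contrast_Ring")),
        }, toxicity=0.20),
        TreatmentSpec("doseresp_3", effects={
            "DNA_TotalIntensity_Circ": Effect(g1_shift=-0.30),
            "Nuc_Elongation_Circ": Effect(shift=1.2 * m("Nuc_Elongation_Circ")),
        }, toxicity=0.15),
        TreatmentSpec("doseinsens_1", ec50=0.05, effects={
            "RNA_AvgIntensity_Ring": Effect(shift=2.0 * m("RNA_AvgIntensity_Ring")),
            "Lyso_SpotCount_Ring": Effect(scale=1.5),
            "Peroxi_SpotCount_Ring": Effect(shift=1.6 * m("Peroxi_SpotCount_Ring")),
        }),
        TreatmentSpec("toxic_1", hill=4.0, ec50=1.25, toxicity=0.85, effects={
            "Mito_TotalIntensity_Ring": Effect(shift=4.0 * m("Mito_TotalIntensity_Ring")),
            "Nuc_Area_Circ": Effect(shift=3.0 * m("Nuc_Area_Circ")),
            "Cell_Area_Ring": Effect(shift=3.0 * m("Cell_Area_Ring")),
            "DNA_Texture_Entropy_Circ": Effect(shift=2.0 * m("DNA_Texture_Entropy_Circ")),
            "RNA_AvgIntensity_Ring": Effect(tail=0.5),
        }),
        TreatmentSpec("toxic_2", hill=4.0, ec50=0.625, toxicity=0.90, effects={
            "PMG_AvgIntensity_Ring": Effect(shift=3.5 * m("PMG_AvgIntensity_Ring")),
            "Nuc_Elongation_Circ": Effect(shift=2.5 * m("Nuc_Elongation_Circ")),
            "DNA_TotalIntensity_Circ": Effect(g1_shift=-0.25),
            "Peroxi_SpotCount_Ring": Effect(shift=2.0 * m("Peroxi_SpotCount_Ring")),
        }),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale active screen: 14 features, 8 compounds, 2 plate positions,
    3 replicates, ~100-300 cells/well."""
    features = default_features()
    return SimulationConfig(
        seed=seed,
        features=features,
        treatments=default_treatments(features),
        counts=CountSpec(mean=170.0, dispersion=50.0, lo=100, hi=300),
    )


def null_config(seed: int = 0, n_features: int = 6, n_compounds: int = 4,
                cells_per_well: float = 120.0) -> SimulationConfig:
    """Null screen: no positional artifacts, no plate effects, no treatment
    effects, no toxicity — treatment and control wells are exchangeable."""
    features = tuple(
        f for f in default_features()[:n_features]
    )
    features = tuple(replace(f, well_jitter=0.0) for f in features)
    return SimulationConfig(
        seed=seed,
        features=features,
        treatments=tuple(TreatmentSpec(f"null_{i + 1}") for i in range(n_compounds)),
        positional=PositionalSpec(amplitudes={}, plate_magnitude_range=(1.0, 1.0)),
        plate_effect=PlateEffectSpec(offset_sd=0.0, scale_sd=0.0),
        counts=CountSpec(mean=cells_per_well, dispersion=50.0,
                         lo=int(cells_per_well * 0.6), hi=int(cells_per_well * 1.6)),
    )


def full_config(seed: int = 0) -> SimulationConfig:
    """Full-size structural analog of the published design: 174 features,
    65 compounds x 7 concentrations split 33/32 across two plate positions,
    paper-calibrated cell counts.  Feature specs and effects are generated
    programmatically (structural, not the assay's actual feature list)."""
    rng = np.random.default_rng(seed + 174)
    markers = ["DNA", "RNA", "PMG", "mitochondria", "lysosome", "peroxisome",
               "lipid", "ER", "actin", "tubulin"]
    classes = ["intensity", "shape", "texture", "spot"]
    feats = []
    for i in range(174):
        marker = markers[i % len(markers)]
        fclass = classes[(i // len(markers)) % len(classes)]
        comp = "Circ" if i % 2 == 0 else "Ring"
        mu = float(rng.uniform(1, 10))
        sd = float(rng.uniform(0.2, 2.0))
        feats.append(FeatureSpec(f"{marker}_{fclass}_{i:03d}_{comp}", fclass,
                                 Gaussian(mu, sd), marker, comp))
    features = tuple(feats)
    treatments = []
    feat_names = [f.name for f in features]
    for i in range(65):
        k = int(rng.integers(0, 6))
        chosen = rng.choice(feat_names, size=k, replace=False) if k else []
        effects = {name: Effect(shift=float(rng.uniform(0.5, 3.0)) * _mad_of(features, name))
                   for name in chosen}
        treatments.append(TreatmentSpec(f"cpd_{i + 1:02d}", effects=effects,
                                        toxicity=float(rng.uniform(0, 0.9)) if i % 7 == 0 else 0.0))
    return SimulationConfig(seed=seed, features=features, treatments=tuple(treatments),
                            counts=paper_count_spec())
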