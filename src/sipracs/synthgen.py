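"""Synthetic data generators for the SIP-RACS analysis chain.

Every downstream stage — Raman classification, REF screening, kinetics — is
exercised on data produced here, with the statistical structure the analysis
assumes:

* single-cell Raman spectra as sums of Gaussian bands on a 500-2000 cm-1 grid
  with a fluorescence-like polynomial background and i.i.d. Gaussian noise; a
  labeled cell's Amide III band (1105 cm-1) is red-shifted by -23 cm-1;
* paired 12C/13C gradient-fraction ASV tables in which only active ASVs in
  the 13C treatment move abundance mass from light to heavy fractions;
* first-order decay series C(t) = C0 exp(-k t) with truncated Gaussian noise;
* enzyme panels with a planted linear relation to removal percent.

All randomness flows through one explicit integer seed per call; identical
seed and design give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .kinetics import DecaySeries, EnzymePanel
from .raman import AMIDE_III_UNLABELED, RamanSpectrum
from .sip import HEAVY_WINDOW, LIGHT_WINDOW, FractionTable

__all__ = [
    "PeakModel",
    "SIPDesign",
    "DecayDesign",
    "DEFAULT_COMPONENTS",
    "DEFAULT_BASELINE_COEFFS",
    "make_spectrum",
    "make_screen_cohort",
    "make_sip_experiment",
    "expected_fraction_compositions",
    "make_decay_series",
    "make_enzyme_panel",
]

#: Default unlabeled band set: phenylalanine ring (1003), Amide III (1105),
#: CH2 deformation (1450), Amide I (1660).  Only Amide III is load-bearing for
#: the labeling call; the others make preprocessing and localization
#: non-trivial.  Tuples are (center cm-1, width cm-1 as std-dev, amplitude).
DEFAULT_COMPONENTS = (
    (1003.0, 6.0, 0.6),
    (1105.0, 8.0, 1.0),
    (1450.0, 10.0, 0.8),
    (1660.0, 9.0, 0.9),
)

#: Fluorescence-like background: convex, decaying over the acquisition window
#: (polynomial in wavenumber, ascending coefficient order).
DEFAULT_BASELINE_COEFFS = (1.2, -9.0e-4, 1.8e-7)


@dataclass(frozen=True)
class PeakModel:
    """Generative model for one cell's Raman spectrum.

    ``label_shift`` is applied to the component whose center is closest to the
    Amide III reference when ``labeled`` is True; partial labeling
    (``label_fraction`` < 1) splits that band's amplitude between the shifted
    and unshifted positions.
    """

    components: tuple = DEFAULT_COMPONENTS
    baseline_coeffs: tuple = DEFAULT_BASELINE_COEFFS
    noise_sd: float = 0.02  # 2% of the Amide III amplitude
    labeled: bool = False
    label_shift: float = -23.0  # cm-1, signed
    label_fraction: float = 1.0
    lineshape: str = "gaussian"  # or "lorentzian"
    grid: tuple[float, float, float] = (500.0, 2000.0, 1.0)  # lo, hi, step

    def __post_init__(self):
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ParameterError("grid must satisfy lo < hi and step > 0")
        for center, width, amp in self.components:
            if width <= 0:
                raise ParameterError(f"component width must be > 0 (center {center})")
            if amp < 0:
                raise ParameterError(f"component amplitude must be >= 0 (center {center})")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0.0 <= self.label_fraction <= 1.0):
            raise ParameterError("label_fraction must lie in [0, 1]")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ParameterError(f"unknown lineshape {self.lineshape!r}")

    def wavenumber_grid(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def _line(x: np.ndarray, center: float, width: float, amp: float, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    return amp * width**2 / ((x - center) ** 2 + width**2)


def make_spectrum(
    model: PeakModel,
    seed: int,
    cell_id: str = "",
    treatment: str | None = None,
) -> RamanSpectrum:
    """Draw one spectrum from a peak model.

    Each component contributes one band; if the model is labeled, the Amide
    III component is translated by ``label_shift`` (partial labeling is a
    mixture of shifted and unshifted bands weighted by ``label_fraction``).
    The polynomial baseline and i.i.d. Gaussian noise are then added.
    """
    rng = np.random.default_rng(seed)
    x = model.wavenumber_grid()
    y = np.zeros_like(x)
    amide_idx = None
    if model.labeled and model.components:
        centers = [c for c, _, _ in model.components]
        amide_idx = int(np.argmin(np.abs(np.asarray(centers) - AMIDE_III_UNLABELED)))
    for i, (center, width, amp) in enumerate(model.components):
        if i == amide_idx:
            f = model.label_fraction
            y += _line(x, center + model.label_shift, width, amp * f, model.lineshape)
            y += _line(x, center, width, amp * (1.0 - f), model.lineshape)
        else:
            y += _line(x, center, width, amp, model.lineshape)
    y += np.polynomial.polynomial.polyval(x, model.baseline_coeffs)
    if model.noise_sd > 0:
        y += rng.normal(0.0, model.noise_sd, size=x.size)
    if treatment is None:
        treatment = "13C" if model.labeled else "12C"
    return RamanSpectrum(
        wavenumbers=x,
        intensities=y,
        cell_id=cell_id,
        treatment=treatment,
        state=frozenset({"raw"}),
    )


def make_screen_cohort(
    n_cells: int = 150,
    n_labeled: int = 10,
    noise_sd: float = 0.02,
    seed: int = 0,
    model: PeakModel | None = None,
) -> list[RamanSpectrum]:
    """Simulate a single-cell screening cohort from one 13C microcosm.

    ``n_labeled`` of the ``n_cells`` hyphae carry the full -23 cm-1 Amide III
    shift (active degraders that assimilated the label); the rest are
    unlabeled.  Which cells are labeled is a seeded permutation; every cell
    gets an independent noise seed.  All cells carry the "13C" treatment tag
    because they come from the labeled microcosm — the label state is what the
    classifier must recover.
    """
    if not (0 <= n_labeled <= n_cells):
        raise ParameterError("need 0 <= n_labeled <= n_cells")
    base = model or PeakModel()
    rng = np.random.default_rng(seed)
    labeled_mask = np.zeros(n_cells, dtype=bool)
    labeled_mask[rng.permutation(n_cells)[:n_labeled]] = True
    seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    cohort = []
    for i in range(n_cells):
        m = PeakModel(
            components=base.components,
            baseline_coeffs=base.baseline_coeffs,
            noise_sd=noise_sd,
            labeled=bool(labeled_mask[i]),
            label_shift=base.label_shift,
            label_fraction=base.label_fraction,
            lineshape=base.lineshape,
            grid=base.grid,
        )
        cohort.append(
            make_spectrum(m, int(seeds[i]), cell_id=f"cell_{i + 1:04d}", treatment="13C")
        )
    return cohort


def _default_abundances(n_asvs: int) -> np.ndarray:
    """Mildly uneven rank-abundance baseline: geometric with ratio 0.98.

    Kept close to even so that every taxon's Dirichlet pseudo-count
    (dispersion * abundance) stays large enough for the REF screen's
    false-positive control to hold at the default dispersion; a long-tailed
    community would make rare-taxon REF estimates arbitrarily noisy.
    """
    v = 0.98 ** np.arange(n_asvs, dtype=float)
    return v / v.sum()


@dataclass(frozen=True)
class SIPDesign:
    """Design of a paired 12C/13C gradient-fractionation experiment.

    Each ASV's DNA mass splits between heavy and light fractions with heavy
    share ``p_heavy_baseline`` in both treatments; an active ASV in the 13C
    treatment shifts toward ``p_heavy_labeled`` in proportion to
    ``labeling_strength``.  Replicate compositions are symmetric-Dirichlet
    perturbations of the expected composition with concentration
    ``dispersion`` (larger = tighter), which preserves the sum-to-one
    constraint exactly.
    """

    n_asvs: int = 20
    baseline_abundances: tuple | None = None  # defaults to 1/rank, normalized
    active_ids: frozenset = frozenset({1})  # 1-based ASV indices
    labeling_strength: float = 1.0
    n_replicates: int = 6  # per (treatment, fraction class)
    dispersion: float = 500.0
    p_heavy_baseline: float = 0.1  # heavy:light 1:9 for unlabeled DNA
    p_heavy_labeled: float = 0.9  # heavy:light 9:1 for fully labeled DNA
    seed: int = 0

    def __post_init__(self):
        if self.n_asvs < 1:
            raise ParameterError("n_asvs must be >= 1")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if not (0.0 <= self.labeling_strength <= 1.0):
            raise ParameterError("labeling_strength must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        for p in (self.p_heavy_baseline, self.p_heavy_labeled):
            if not (0.0 < p < 1.0):
                raise ParameterError("heavy partition shares must lie in (0, 1)")
        bad = [i for i in self.active_ids if not (1 <= i <= self.n_asvs)]
        if bad:
            raise ParameterError(f"active ASV indices out of range: {bad}")
        if self.baseline_abundances is not None:
            b = np.asarray(self.baseline_abundances, dtype=float)
            if b.size != self.n_asvs or np.any(b < 0) or abs(b.sum() - 1.0) > 1e-9:
                raise ParameterError(
                    "baseline_abundances must be a length-n_asvs simplex vector"
                )

    def abundances(self) -> np.ndarray:
        if self.baseline_abundances is not None:
            return np.asarray(self.baseline_abundances, dtype=float)
        return _default_abundances(self.n_asvs)

    def heavy_share(self, asv_index: int, treatment: str) -> float:
        """Expected heavy-fraction share of one ASV's DNA mass."""
        if treatment == "13C" and asv_index in self.active_ids:
            s = self.labeling_strength
            return (1.0 - s) * self.p_heavy_baseline + s * self.p_heavy_labeled
        return self.p_heavy_baseline


def expected_fraction_compositions(design: SIPDesign) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free expected composition of each (treatment, fraction class).

    The expected relative abundance of ASV i in, say, a 13C heavy sample is
    its heavy mass divided by the total heavy mass over all ASVs — moving one
    ASV's mass between fraction classes renormalizes everyone else, which is
    exactly the compositional behaviour REF must be robust to.
    """
    b = design.abundances()
    out: dict[tuple[str, str], np.ndarray] = {}
    for treatment in ("12C", "13C"):
        shares = np.array(
            [design.heavy_share(i + 1, treatment) for i in range(design.n_asvs)]
        )
        heavy_mass = b * shares
        light_mass = b * (1.0 - shares)
        out[(treatment, "heavy")] = heavy_mass / heavy_mass.sum()
        out[(treatment, "light")] = light_mass / light_mass.sum()
    return out


def make_sip_experiment(design: SIPDesign) -> tuple[FractionTable, FractionTable]:
    """Simulate one paired fractionation experiment -> (12C table, 13C table).

    For every treatment x fraction class, ``n_replicates`` sample compositions
    are drawn as Dirichlet(dispersion * expected composition); buoyant
    densities are drawn uniformly inside the corresponding density window.
    """
    rng = np.random.default_rng(design.seed)
    expected = expected_fraction_compositions(design)
    asv_ids = [f"ASV_{i + 1}" for i in range(design.n_asvs)]
    windows = {"heavy": HEAVY_WINDOW, "light": LIGHT_WINDOW}

    tables = {}
    for treatment in ("12C", "13C"):
        sample_rows = []
        columns = {}
        for cls in ("light", "heavy"):
            mean = expected[(treatment, cls)]
            for r in range(1, design.n_replicates + 1):
                sid = f"{treatment}_{cls}_r{r}"
                if design.n_asvs == 1:
                    comp = np.array([1.0])
                else:
                    comp = rng.dirichlet(design.dispersion * mean)
                    comp = comp / comp.sum()  # exact simplex closure
                lo, hi = windows[cls]
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "replicate": r,
                        "fraction_class": cls,
                        "density_g_ml": float(rng.uniform(lo, hi)),
                    }
                )
                columns[sid] = comp
        samples = pd.DataFrame(sample_rows).set_index("sample_id")
        abundance = pd.DataFrame(columns, index=asv_ids)
        tables[treatment] = FractionTable(
            treatment=treatment, samples=samples, abundance=abundance
        )
    return tables["12C"], tables["13C"]


@dataclass(frozen=True)
class DecayDesign:
    """First-order decay series design.

    Defaults reproduce the native-soil microcosm conditions: 5 mg/kg starting
    concentration falling to 2.01 mg/kg by day 7 (k = ln(5/2.01)/7 per day),
    sampled at days 0, 7 and 14 in six replicates.
    """

    c0: float = 5.0
    k: float = math.log(5.0 / 2.01) / 7.0  # per day
    times: tuple = (0.0, 7.0, 14.0)
    noise_sd: float = 0.25  # concentration units (5% of default C0)
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self):
        if not self.c0 > 0:
            raise ParameterError("C0 must be positive")
        if self.k < 0:
            raise ParameterError("first-order k must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if np.any(t < 0) or (t.size >= 2 and not np.all(np.diff(t) > 0)):
            raise ParameterError("times must be nonnegative and increasing")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


def make_decay_series(
    design: DecayDesign, treatment: str = "NS", units: str = "mg/kg"
) -> DecaySeries:
    """Simulate C(t) = C0 exp(-k t) plus truncated-at-zero Gaussian noise."""
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.times, dtype=float)
    clean = design.c0 * np.exp(-design.k * t)
    c = np.tile(clean[:, None], (1, design.n_replicates))
    if design.noise_sd > 0:
        c = c + rng.normal(0.0, design.noise_sd, size=c.shape)
    c = np.clip(c, 0.0, None)
    return DecaySeries(times=t, concentrations=c, treatment=treatment, units=units)


def make_enzyme_panel(
    slope: float,
    intercept: float,
    noise_sd: float,
    removals: np.ndarray,
    seed: int,
    enzyme: str = "LiP",
    units: str = "U/ml",
) -> EnzymePanel:
    """Enzyme activities with a planted linear relation to removal percent.

    activity = slope * removal + intercept + Gaussian noise, clipped at zero
    (activities cannot be negative).
    """
    removals = np.asarray(removals, dtype=float)
    if np.any((removals < 0) | (removals > 100)):
        raise ParameterError("removals must lie in [0, 100] percent")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    act = slope * removals + intercept
    if noise_sd > 0:
        act = act + rng.normal(0.0, noise_sd, size=removals.size)
    act = np.clip(act, 0.0, None)
    return EnzymePanel(enzyme=enzyme, activities=act, units=units)
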