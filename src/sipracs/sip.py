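"""DNA-SIP relative enrichment factor (REF) screening of ASV fraction tables.

After feeding a 13C-labeled substrate, organisms that assimilate the label
build denser DNA, which migrates to heavier CsCl-gradient fractions.  With a
parallel 12C control, a taxon's enrichment is the ratio of its heavy/light
relative-abundance ratios across the two treatments:

    REF = (13C_heavy / 13C_light) / (12C_heavy / 12C_light)

where each term is the taxon's mean relative abundance over replicate samples
of that (treatment, fraction class).  Taxa with REF above a threshold and
non-trivial abundance are called active degraders.  Density windows follow the
standard gradient fractionation: "light" 1.7042-1.7089 g/ml and "heavy"
1.7342-1.7411 g/ml; samples outside both windows are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

__all__ = [
    "LIGHT_WINDOW",
    "HEAVY_WINDOW",
    "FractionTable",
    "REFRecord",
    "ScreenConfig",
    "assign_fraction_class",
    "compute_ref",
    "screen_active",
    "bootstrap_ref",
]

LIGHT_WINDOW = (1.7042, 1.7089)
HEAVY_WINDOW = (1.7342, 1.7411)

_SUM_TOL = 1e-9


def assign_fraction_class(density: float) -> str:
    """Map a buoyant density (g/ml) to "heavy", "light" or "excluded".

    Window membership is inclusive on both ends; densities between or outside
    the two windows are excluded from REF computation rather than assigned to
    the nearest window.
    """
    if not density > 0:
        raise InputError("buoyant density must be positive")
    if HEAVY_WINDOW[0] <= density <= HEAVY_WINDOW[1]:
        return "heavy"
    if LIGHT_WINDOW[0] <= density <= LIGHT_WINDOW[1]:
        return "light"
    return "excluded"


@dataclass
class FractionTable:
    """ASV x gradient-fraction relative abundances for one treatment.

    ``samples`` is indexed by sample id with columns ``replicate``,
    ``fraction_class`` and ``density_g_ml``; ``abundance`` is an ASV-by-sample
    DataFrame whose columns match the sample index and each sum to 1.
    """

    treatment: str  # "12C" or "13C"
    samples: pd.DataFrame
    abundance: pd.DataFrame

    def __post_init__(self):
        if self.treatment not in ("12C", "13C"):
            raise InputError(f"treatment must be '12C' or '13C', got {self.treatment!r}")
        missing = {"replicate", "fraction_class"} - set(self.samples.columns)
        if missing:
            raise InputError(f"samples table missing columns: {sorted(missing)}")
        if list(self.abundance.columns) != list(self.samples.index):
            raise InputError("abundance columns must match the sample index")
        sums = self.abundance.sum(axis=0)
        bad = sums[(sums - 1.0).abs() > _SUM_TOL]
        if len(bad):
            raise InputError(
                f"sample(s) {list(bad.index)} have abundances summing to "
                f"{bad.iloc[0]:.6g}, expected 1"
            )
        if "density_g_ml" in self.samples.columns:
            for sid, row in self.samples.iterrows():
                expected = assign_fraction_class(float(row["density_g_ml"]))
                if row["fraction_class"] != expected:
                    raise InputError(
                        f"sample {sid}: fraction_class {row['fraction_class']!r} "
                        f"inconsistent with density {row['density_g_ml']} ({expected})"
                    )

    def class_columns(self, fraction_class: str) -> list:
        return list(self.samples.index[self.samples["fraction_class"] == fraction_class])

    def class_means(self, fraction_class: str) -> pd.Series:
        """Mean relative abundance per ASV over replicates of one class."""
        cols = self.class_columns(fraction_class)
        if not cols:
            raise InputError(
                f"treatment {self.treatment}: no '{fraction_class}' fraction samples"
            )
        return self.abundance[cols].mean(axis=1)


@dataclass
class REFRecord:
    """Per-ASV REF statistic and the four mean abundances behind it.

    The ``a*`` fields are the raw fraction-class means (before any
    pseudocount); ``ref`` is computed from pseudocount-adjusted terms when a
    raw term is zero.  ``mean_abundance`` is the mean of the four raw terms.
    """

    asv_id: str
    a13_heavy: float
    a13_light: float
    a12_heavy: float
    a12_light: float
    ref: float
    mean_abundance: float
    active: bool = False


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and zero-handling policy for the active-taxon screen."""

    abundance_min: float = 0.005  # gate: mean abundance must exceed 0.5%
    ref_min: float = 1.5  # gate: REF must exceed 1.5
    pseudocount_policy: str = "half_min_nonzero"  # or "fixed"
    fixed_pseudocount: float = 1e-6

    def __post_init__(self):
        if self.abundance_min <= 0 or self.ref_min <= 0:
            raise ParameterError("screen thresholds must be positive")
        if self.pseudocount_policy not in ("half_min_nonzero", "fixed"):
            raise ParameterError(
                f"unknown pseudocount policy {self.pseudocount_policy!r}"
            )
        if self.pseudocount_policy == "fixed" and self.fixed_pseudocount <= 0:
            raise ParameterError("fixed_pseudocount must be positive")


def _term_matrix(t12: FractionTable, t13: FractionTable) -> pd.DataFrame:
    """Four fraction-class mean columns (rows = ASVs, aligned universes)."""
    if set(t12.abundance.index) != set(t13.abundance.index):
        raise InputError("12C and 13C tables cover different ASV universes")
    order = list(t13.abundance.index)
    return pd.DataFrame(
        {
            "a13_heavy": t13.class_means("heavy").reindex(order),
            "a13_light": t13.class_means("light").reindex(order),
            "a12_heavy": t12.class_means("heavy").reindex(order),
            "a12_light": t12.class_means("light").reindex(order),
        }
    )


def compute_ref(
    t12: FractionTable,
    t13: FractionTable,
    cfg: ScreenConfig | None = None,
) -> list[REFRecord]:
    """Compute one REF per ASV from paired 12C/13C fraction tables.

    Replicate samples are averaged within each (treatment, fraction class)
    before forming ratios.  Any ASV with a zero among its four terms has the
    pseudocount added to all four terms before the ratio (half the smallest
    nonzero term in the combined table under the default policy), which keeps
    REF finite and symmetric; the stored term fields stay un-adjusted.
    """
    cfg = cfg or ScreenConfig()
    if t12.treatment != "12C" or t13.treatment != "13C":
        raise InputError("compute_ref expects (12C table, 13C table) in that order")
    terms = _term_matrix(t12, t13)

    values = terms.to_numpy()
    nonzero = values[values > 0]
    if cfg.pseudocount_policy == "half_min_nonzero":
        if nonzero.size == 0:
            raise InputError("all abundance terms are zero; cannot form REF")
        pseudocount = 0.5 * float(nonzero.min())
    else:
        pseudocount = cfg.fixed_pseudocount

    records: list[REFRecord] = []
    for asv_id, row in terms.iterrows():
        raw = row.to_numpy(dtype=float)
        adj = raw + pseudocount if np.any(raw == 0.0) else raw
        ref = (adj[0] / adj[1]) / (adj[2] / adj[3])
        records.append(
            REFRecord(
                asv_id=str(asv_id),
                a13_heavy=float(raw[0]),
                a13_light=float(raw[1]),
                a12_heavy=float(raw[2]),
                a12_light=float(raw[3]),
                ref=float(ref),
                mean_abundance=float(raw.mean()),
            )
        )
    return records


def screen_active(
    records: list[REFRecord], cfg: ScreenConfig | None = None
) -> list[REFRecord]:
    """Flag active taxa: mean abundance AND REF strictly above their gates.

    Both inequalities are strict (a REF of exactly ``ref_min`` is not active).
    Records are flagged in place; the active subset is returned sorted by
    descending REF.
    """
    cfg = cfg or ScreenConfig()
    for r in records:
        r.active = (r.mean_abundance > cfg.abundance_min) and (r.ref > cfg.ref_min)
    return sorted((r for r in records if r.active), key=lambda r: -r.ref)


def bootstrap_ref(
    t12: FractionTable,
    t13: FractionTable,
    cfg: ScreenConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile intervals for REF by resampling replicate samples.

    Resamples, with replacement, the sample columns within every
    (treatment, fraction class) stratum ``n_boot`` times and recomputes REF
    for each draw.  Returns a DataFrame indexed by ASV with the 2.5th, 50th
    and 97.5th percentiles of the bootstrap REF distribution.
    """
    cfg = cfg or ScreenConfig()
    rng = np.random.default_rng(seed)
    strata = {
        (table.treatment, cls): table.class_columns(cls)
        for table in (t12, t13)
        for cls in ("heavy", "light")
    }
    asvs = list(t13.abundance.index)
    draws = np.empty((n_boot, len(asvs)))
    for b in range(n_boot):
        resampled = {}
        for (treatment, cls), cols in strata.items():
            pick = [cols[i] for i in rng.integers(0, len(cols), size=len(cols))]
            table = t13 if treatment == "13C" else t12
            resampled[(treatment, cls)] = table.abundance[pick].mean(axis=1)
        t = pd.DataFrame(
            {
                "a13_heavy": resampled[("13C", "heavy")],
                "a13_light": resampled[("13C", "light")],
                "a12_heavy": resampled[("12C", "heavy")],
                "a12_light": resampled[("12C", "light")],
            }
        ).reindex(asvs)
        vals = t.to_numpy()
        nz = vals[vals > 0]
        pc = 0.5 * float(nz.min()) if nz.size else cfg.fixed_pseudocount
        adj = np.where(
            (vals == 0).any(axis=1, keepdims=True), vals + pc, vals
        )
        draws[b] = (adj[:, 0] / adj[:, 1]) / (adj[:, 2] / adj[:, 3])
    pct = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {"ref_lo": pct[0], "ref_median": pct[1], "ref_hi": pct[2]}, index=asvs
    )
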