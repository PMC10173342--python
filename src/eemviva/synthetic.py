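"""Synthetic EEM study generator.

Emulates a two-cell-line oxaliplatin dose-response fluorescence study:
2 cell lines x 6 dose groups x 12 replicates = 144 samples, each an EEM on
the default acquisition grid (71 emission x 26 excitation points with the
protocol's triangular unmeasured region).  Five trilinear fluorophore
components with literature-plausible spectral maxima drive the signal;
their per-sample concentrations (scores) move monotonically with viability
— components 1, 4 and 5 fall as viability falls, components 2 and 3 rise —
so that a linear score-to-viability calibration is the correct model.  An
MTT viability reference (percent of control, 5 replicates per group) is
generated alongside.

Everything is fully determined by (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .grid import EEMCube, EEMGrid, build_acquisition_grid
from .parafac import ParafacModel, canonicalize

CELL_LINE_DOSES: dict[str, tuple[float, ...]] = {
    "A375": (0, 5, 50, 250, 500, 1000),
    "HaCaT": (0, 5, 25, 100, 250, 500),
}

N_FLUOR_REPLICATES = 12
N_MTT_REPLICATES = 5

#: Dose (uM) -> approximate MTT viability (% of control) per cell line.
DEFAULT_VIABILITY: dict[str, dict[float, float]] = {
    "A375": {0: 100, 5: 90, 50: 80, 250: 60, 500: 10, 1000: 10},
    "HaCaT": {0: 100, 5: 90, 25: 70, 100: 65, 250: 50, 500: 10},
}

#: Per-component (baseline, slope) of mean score vs viability (%).  Positive
#: slopes for components 1, 4, 5 (concentration falls with falling
#: viability); negative for components 2 and 3 (rises as cells die).
#: Relative magnitudes follow the described intensity landscape of such
#: cultures: the tryptophan-like protein signal dominates the landscape,
#: the remaining fluorophores contribute at several-fold lower intensity.
DEFAULT_TREND_PARAMS: tuple[tuple[float, float], ...] = (
    (3.0, 0.17),     # component 1: tryptophan-like, dominant protein signal
    (2.2, -0.012),   # component 2: tyrosine-like
    (1.2, -0.005),   # component 3: pyridoxine-like
    (0.5, 0.025),    # component 4: bimodal flavin/porphyrin-like
    (0.8, 0.032),    # component 5: NADH-like
)


@dataclass(frozen=True)
class FluorophorePrototype:
    """Ground-truth fluorophore: sums of Gaussian bands per mode.

    Bands are (center nm, width sigma nm, weight) triples; profiles are
    evaluated on a grid, clipped at zero and normalized to unit Euclidean
    norm.  Emission centers sit above excitation centers (Stokes shift).

    Symmetric Gaussian tails would overlap across the Rayleigh line and
    imply appreciable intensity at Stokes shifts below the protocol's
    scatter gap, which real fluorophores do not show: absorption bands end
    sharply on their red edge and emission bands rise from an onset just
    above it.  ``excitation_cutoff`` and ``emission_onset`` taper the
    profiles smoothly (5 nm logistic edge) to enforce that Stokes gap.
    """

    name: str
    excitation_bands: tuple[tuple[float, float, float], ...]
    emission_bands: tuple[tuple[float, float, float], ...]
    excitation_cutoff: float | None = None
    emission_onset: float | None = None
    edge_width: float = 5.0

    def __post_init__(self):
        if not self.excitation_bands or not self.emission_bands:
            raise ValueError("prototype needs at least one band per mode")
        if any(w <= 0 for *_, w in self.excitation_bands + self.emission_bands):
            raise ValueError("band weights must be positive")
        if min(c for c, *_ in self.emission_bands) <= min(c for c, *_ in self.excitation_bands):
            raise ValueError("emission centers must lie above excitation centers (Stokes shift)")

    def _profile(self, bands, wavelengths: np.ndarray, *, onset=None, cutoff=None) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        y = np.zeros_like(wl)
        for center, sigma, weight in bands:
            y += weight * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        if onset is not None:
            y *= 1.0 / (1.0 + np.exp(-(wl - onset) / self.edge_width))
        if cutoff is not None:
            y *= 1.0 / (1.0 + np.exp((wl - cutoff) / self.edge_width))
        n = np.linalg.norm(y)
        if n == 0:
            raise ValueError("profile vanishes on the supplied grid")
        return y / n

    def emission_profile(self, em_wavelengths: np.ndarray) -> np.ndarray:
        return self._profile(self.emission_bands, em_wavelengths, onset=self.emission_onset)

    def excitation_profile(self, ex_wavelengths: np.ndarray) -> np.ndarray:
        return self._profile(self.excitation_bands, ex_wavelengths, cutoff=self.excitation_cutoff)


def default_prototypes(grid: EEMGrid, band_sigma: float | None = None
                       ) -> list[FluorophorePrototype]:
    """Five fluorophore prototypes at the study's spectral maxima.

    Peak positions: 290/330 (tryptophan-like), 280/310 (tyrosine-like;
    emission placed below 325 nm), 300/380 (pyridoxine-like), bimodal
    390&440/520&590 (flavin/porphyrin-like), 360/450 (NADH-like).

    Default band widths follow typical fluorophore band shapes: narrow
    aromatic-amino-acid UV bands (sigma 12-18 nm) and broader visible
    coenzyme/porphyrin bands (sigma 20 nm).  Narrow UV bands also keep the
    spectral mass of the small-Stokes-shift components out of the protocol's
    never-measured scatter triangle, so the masked-and-refilled cube retains
    its trilinear structure.  Passing ``band_sigma`` overrides every width
    with one value for sensitivity studies.
    """
    def w(default: float) -> float:
        return float(band_sigma) if band_sigma is not None else default

    protos = [
        FluorophorePrototype("tryptophan-like", ((290, w(13), 1.0),), ((330, w(18), 1.0),),
                             excitation_cutoff=308, emission_onset=312),
        FluorophorePrototype("tyrosine-like", ((280, w(12), 1.0),), ((310, w(12), 1.0),),
                             excitation_cutoff=295, emission_onset=297),
        FluorophorePrototype("pyridoxine-like", ((300, w(15), 1.0),), ((380, w(20), 1.0),)),
        FluorophorePrototype(
            "flavin-porphyrin-like",
            ((390, w(20), 1.0), (440, w(20), 0.9)),
            ((520, w(20), 1.0), (590, w(20), 0.9)),
        ),
        FluorophorePrototype("NADH-like", ((360, w(20), 1.0),), ((450, w(20), 1.0),)),
    ]
    for p in protos:
        for bands, axis, mode in ((p.excitation_bands, grid.ex_wavelengths, "excitation"),
                                  (p.emission_bands, grid.em_wavelengths, "emission")):
            for c, sig, _ in bands:
                if c - 2 * sig < axis[0] or c + 2 * sig > axis[-1]:
                    logger.debug(
                        "%s %s band at %g nm (sigma %g) is truncated by the grid",
                        p.name, mode, c, sig)
    return protos


def generate_design(doses: dict[str, tuple[float, ...]] | None = None,
                    n_replicates: int = N_FLUOR_REPLICATES) -> pd.DataFrame:
    """Sample metadata table: every (cell line, dose, replicate) combination.

    Defaults give 2 lines x 6 doses x 12 replicates = 144 rows.
    """
    doses = doses if doses is not None else CELL_LINE_DOSES
    rows = []
    for line, ds in doses.items():
        for d in ds:
            for r in range(1, n_replicates + 1):
                rows.append((line, float(d), r))
    df = pd.DataFrame(rows, columns=["cell_line", "dose_uM", "replicate"])
    df.insert(0, "sample_id", np.arange(len(df)))
    return df


def viability_map(cell_line: str, dose_uM: float,
                  table: dict[str, dict[float, float]] | None = None) -> float:
    """Mean viability (% of control) for a (cell line, dose) group."""
    table = table if table is not None else DEFAULT_VIABILITY
    try:
        return float(table[cell_line][float(dose_uM)])
    except KeyError:
        raise KeyError(f"no viability defined for ({cell_line!r}, {dose_uM} uM)") from None


def generate_scores(design: pd.DataFrame,
                    trend_params: tuple[tuple[float, float], ...] = DEFAULT_TREND_PARAMS,
                    noise_cv: float = 0.03,
                    drift_per_replicate: float = 0.0,
                    inner_filter_attenuation: float = 0.0,
                    seed: int | None = 0,
                    viability_table: dict | None = None,
                    allow_any_slopes: bool = False) -> np.ndarray:
    """True component scores, linear in viability with replicate noise.

    ``score_if = baseline_f + slope_f * viability_i``, perturbed by Gaussian
    replicate noise of coefficient of variation ``noise_cv`` and truncated
    at zero.  Slope signs must follow the component trends (positive for
    components 1, 4, 5; negative for 2, 3) unless ``allow_any_slopes``.

    Optional effects, both off by default: a linear drift in the replicate
    index (fraction of the mean per replicate step) and an inner-filter-like
    multiplicative attenuation of component 3 at the lowest viabilities.
    """
    expected_signs = (1, -1, -1, 1, 1)
    if not allow_any_slopes and len(trend_params) == 5:
        for f, ((_, slope), sign) in enumerate(zip(trend_params, expected_signs)):
            if np.sign(slope) != sign:
                raise ValueError(
                    f"slope sign for component {f + 1} contradicts its viability trend; "
                    "pass allow_any_slopes=True to override"
                )
    rng = np.random.default_rng(seed)
    viab = np.array([
        viability_map(r.cell_line, r.dose_uM, viability_table)
        for r in design.itertuples()
    ])
    F = len(trend_params)
    scores = np.empty((len(design), F))
    for f, (baseline, slope) in enumerate(trend_params):
        mean = baseline + slope * viab
        noisy = mean * (1.0 + noise_cv * rng.standard_normal(len(design)))
        if drift_per_replicate:
            noisy *= 1.0 + drift_per_replicate * (design["replicate"].to_numpy() - 1)
        if inner_filter_attenuation and f == 2:
            low = viab <= np.quantile(viab, 0.2)
            noisy[low] *= 1.0 - inner_filter_attenuation
        scores[:, f] = np.maximum(noisy, 0.0)
    return scores


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cube, for recovery assessment."""

    prototypes: list[FluorophorePrototype]
    em_loadings: np.ndarray       # J x F, unit-norm
    ex_loadings: np.ndarray       # K x F, unit-norm
    scores: np.ndarray            # I x F
    viability: np.ndarray         # I, % of control
    noise_rms: float
    seed: int | None
    config: dict = field(default_factory=dict)

    def as_model(self, grid: EEMGrid) -> ParafacModel:
        """The truth packaged as a canonical PARAFAC model for matching."""
        A, B, C = canonicalize(self.scores, self.em_loadings, self.ex_loadings)
        return ParafacModel(F=self.scores.shape[1], scores=A, em_loadings=B,
                            ex_loadings=C, em_wavelengths=grid.em_wavelengths,
                            ex_wavelengths=grid.ex_wavelengths)

    def match_model(self, model: ParafacModel) -> np.ndarray:
        """Map prototype index -> fitted component index by joint congruence.

        The assignment maximizes the summed product of emission and
        excitation Tucker congruences (exact Hungarian assignment), so
        ``perm[f]`` is the fitted component corresponding to prototype ``f``
        in the generator's order.
        """
        from scipy.optimize import linear_sum_assignment

        from .parafac import congruence_matrix

        sim = (congruence_matrix(self.em_loadings, model.em_loadings)
               * congruence_matrix(self.ex_loadings, model.ex_loadings))
        rows, cols = linear_sum_assignment(-sim)
        perm = np.empty(self.scores.shape[1], dtype=int)
        perm[rows] = cols
        return perm


def generate_cube(config: dict | None = None, seed: int | None = 0
                  ) -> tuple[EEMCube, SyntheticTruth]:
    """Generate a masked synthetic EEM cube plus its ground truth.

    The noise-free cube is the exact trilinear combination of the prototype
    spectra and true scores; independent Gaussian noise with RMS equal to
    ``noise_rms_fraction`` (default 0.001, i.e. 0.1%) of the signal RMS is
    added, and cells outside the acquisition mask are deleted (NaN) for the
    preprocessing stage to restore.
    """
    cfg = dict(
        noise_rms_fraction=1e-3,
        band_sigma=None,
        score_noise_cv=0.03,
        drift_per_replicate=0.0,
        inner_filter_attenuation=0.0,
        trend_params=DEFAULT_TREND_PARAMS,
        doses=None,
        n_replicates=N_FLUOR_REPLICATES,
        viability_table=None,
    )
    cfg.update(config or {})
    rng = np.random.default_rng(seed)
    grid = build_acquisition_grid()
    design = generate_design(cfg["doses"], cfg["n_replicates"])
    protos = default_prototypes(grid, cfg["band_sigma"])
    B = np.column_stack([p.emission_profile(grid.em_wavelengths) for p in protos])
    C = np.column_stack([p.excitation_profile(grid.ex_wavelengths) for p in protos])
    scores = generate_scores(
        design,
        trend_params=cfg["trend_params"],
        noise_cv=cfg["score_noise_cv"],
        drift_per_replicate=cfg["drift_per_replicate"],
        inner_filter_attenuation=cfg["inner_filter_attenuation"],
        seed=rng.integers(2**31),
        viability_table=cfg["viability_table"],
    )
    clean = np.einsum("if,jf,kf->ijk", scores, B, C)
    signal_rms = float(np.sqrt((clean ** 2).mean()))
    noise_rms = cfg["noise_rms_fraction"] * signal_rms
    data = clean + noise_rms * rng.standard_normal(clean.shape)
    data[:, ~grid.measured_mask] = np.nan
    viab = np.array([
        viability_map(r.cell_line, r.dose_uM, cfg["viability_table"])
        for r in design.itertuples()
    ])
    cube = EEMCube(grid=grid, data=data, samples=design,
                   provenance={"generator": {"seed": seed,
                                             "noise_rms_fraction": cfg["noise_rms_fraction"]}})
    truth = SyntheticTruth(prototypes=protos, em_loadings=B, ex_loadings=C,
                           scores=scores, viability=viab, noise_rms=noise_rms,
                           seed=seed, config=cfg)
    return cube, truth


def mtt_reference(design: pd.DataFrame, seed: int | None = 0,
                  noise_cv: float = 0.05,
                  n_replicates: int = N_MTT_REPLICATES,
                  viability_table: dict | None = None) -> pd.DataFrame:
    """Simulated MTT viability reference: mean +/- SD per dose group.

    Five replicate absorbance ratios per (cell line, dose) group, Gaussian
    around the group's viability with coefficient of variation ``noise_cv``;
    every group is normalized to its cell line's control mean, so the
    control group mean is exactly 100%.

    Returns a DataFrame with columns ``cell_line, dose_uM, viability_mean,
    viability_sd, n`` and the per-replicate values in ``replicates``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for line in design["cell_line"].unique():
        doses = sorted(design.loc[design.cell_line == line, "dose_uM"].unique())
        raw = {}
        for d in doses:
            v = viability_map(line, d, viability_table)
            raw[d] = v * (1.0 + noise_cv * rng.standard_normal(n_replicates))
        control_mean = raw[0.0].mean() if 0.0 in raw else 100.0
        for d in doses:
            pct = raw[d] / control_mean * 100.0
            rows.append(dict(cell_line=line, dose_uM=d,
                             viability_mean=float(pct.mean()),
                             viability_sd=float(pct.std(ddof=1)),
                             n=n_replicates,
                             replicates=pct.tolist()))
    return pd.DataFrame(rows)
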