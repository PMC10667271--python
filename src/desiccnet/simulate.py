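"""Synthetic multi-omics data with planted, recoverable structure.

Every generator is a pure function of a :class:`SimulationConfig`. The
expression generator plants (a) co-expression modules — groups of genes
sharing a latent Gaussian factor within one tissue, scaled so the
expected within-module Pearson correlation hits ``module_corr`` — and
(b) differential expression: module genes shift by ``deg_log2fc`` in
their active (tissue, state) cells only. The metabolite generator
encodes the early-shoot sugar/amino-acid accumulation and the late-root
amino-acid accumulation; the hormone generator encodes abscisic acid
high in hydrated tissue, salicylic acid rising from 60% RWC, and
jasmonoyl-isoleucine declining through drying.

Ground truth for every planted feature is returned alongside the data
so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "SyntheticTruth",
    "generate_expression",
    "generate_metabolites",
    "generate_hormones",
    "generate_physiology",
    "make_sample_sheet",
    "RWC_BANDS",
]

#: Pre-drying RWC bands for the gradual-then-rapid drying experiment,
#: ordered wettest to driest, plus the hydrated control.
RWC_BANDS = ("100-80", "70-60", "50-40", "30-20", "<10")
BAND_BOUNDS = {
    "100-80": (80.0, 100.0),
    "70-60": (60.0, 70.0),
    "50-40": (40.0, 50.0),
    "30-20": (20.0, 30.0),
    "<10": (0.0, 10.0),
}

# Metabolite panel: the early-accumulating shoot set (sugars, polyols,
# proline) and the late-accumulating root amino-acid set, plus TCA-cycle
# organic acids that stay flat.
EARLY_SHOOT_METABOLITES = (
    "sucrose",
    "raffinose",
    "myo-inositol",
    "galactitol",
    "D-erythritol",
    "proline",
)
LATE_ROOT_METABOLITES = (
    "asparagine",
    "isoleucine",
    "leucine",
    "valine",
    "methionine",
    "tyrosine",
)
FLAT_METABOLITES = (
    "citrate",
    "succinate",
    "malate",
    "fumarate",
    "pyruvate",
    "glucose",
    "fructose",
)

HORMONES = ("ABA", "SA", "JA-Ile")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure.

    Attributes
    ----------
    deg_truth : set of (gene, tissue, state, direction)
        Every planted differential-expression event.
    module_truth : dict
        gene id -> module index (genes outside any module are absent).
    hormone_profile_truth : dict
        hormone -> {state: population mean}.
    metabolite_truth : dict
        metabolite -> {(tissue, state): fold change of the population
        mean relative to hydrated} for planted (non-unit) changes.
    """

    deg_truth: set = field(default_factory=set)
    module_truth: dict = field(default_factory=dict)
    hormone_profile_truth: dict = field(default_factory=dict)
    metabolite_truth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "deg_truth": sorted(list(t) for t in self.deg_truth),
            "module_truth": self.module_truth,
            "hormone_profile_truth": self.hormone_profile_truth,
            "metabolite_truth": {
                m: {f"{t}|{s}": v for (t, s), v in d.items()}
                for m, d in self.metabolite_truth.items()
            },
        }


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stream name)."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the full tissue x state x replicate design."""
    rows = [
        {
            "sample_id": f"{t}_{s}_r{r}",
            "tissue": t,
            "state": s,
            "replicate": r,
        }
        for t in config.tissues
        for s in config.states
        for r in range(1, config.replicates + 1)
    ]
    return pd.DataFrame(rows)


def generate_expression(config: SimulationConfig):
    """Simulate a log2-scale gene x sample expression matrix.

    Returns
    -------
    expr : pandas.DataFrame
        genes x samples, log2 abundance.
    samples : pandas.DataFrame
        sample sheet (sample_id, tissue, state, replicate).
    truth : SyntheticTruth
        planted modules and DEG events.

    Notes
    -----
    Module gene ``g`` in its home tissue follows
    ``x = baseline_g + a * f_sample + eps`` with ``eps ~ N(0, noise_sd^2)``
    and loading ``a = noise_sd * sqrt(rho / (1 - rho))``, which gives an
    expected pairwise within-module correlation of exactly ``rho``.
    Planted DEG shifts of ``+/- deg_log2fc`` are added on top in the
    module's active states.
    """
    samples = make_sample_sheet(config)
    n_samples = len(samples)
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    rng = _rng(config.seed, "expression")
    baselines = rng.uniform(2.0, 12.0, size=config.n_genes)
    x = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )

    truth = SyntheticTruth()
    rho = config.module_corr
    loading = config.noise_sd * np.sqrt(rho / (1.0 - rho))

    tissue_arr = samples["tissue"].to_numpy()
    state_arr = samples["state"].to_numpy()

    for m_idx, mod in enumerate(config.modules):
        lo = m_idx * config.module_size
        member_rows = np.arange(lo, lo + config.module_size)
        for g in member_rows:
            truth.module_truth[genes[g]] = m_idx

        in_tissue = tissue_arr == mod.tissue
        factor = rng.normal(0.0, 1.0, size=int(in_tissue.sum()))
        x[np.ix_(member_rows, np.flatnonzero(in_tissue))] += loading * factor

        shift = config.deg_log2fc if mod.direction == "up" else -config.deg_log2fc
        active = in_tissue & np.isin(state_arr, mod.active_states)
        x[np.ix_(member_rows, np.flatnonzero(active))] += shift
        for g in member_rows:
            for s in mod.active_states:
                truth.deg_truth.add((genes[g], mod.tissue, s, mod.direction))

    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"),
                        columns=samples["sample_id"].to_numpy())
    return expr, samples, truth


def _metabolite_panel(config: SimulationConfig):
    names = list(EARLY_SHOOT_METABOLITES + LATE_ROOT_METABOLITES + FLAT_METABOLITES)
    if config.n_metabolites < len(names):
        names = names[: config.n_metabolites]
    else:
        names += [f"met_{i:03d}" for i in range(1, config.n_metabolites - len(names) + 1)]
    return names


def generate_metabolites(config: SimulationConfig):
    """Simulate a positive metabolite x sample abundance matrix.

    Early-accumulating metabolites (sucrose, raffinose, myo-inositol,
    polyols, proline) are elevated four-fold in shoots from 60% RWC
    onward; the late amino-acid set is elevated four-fold in roots at
    <10% RWC (and halfway there in rehydrated roots). Noise is
    multiplicative lognormal.
    """
    samples = make_sample_sheet(config)
    names = _metabolite_panel(config)
    rng = _rng(config.seed, "metabolites")

    base = rng.uniform(5.0, 50.0, size=len(names))
    truth_fc = {}
    mean = np.tile(base[:, None], (1, len(samples)))

    tissue = samples["tissue"].to_numpy()
    state = samples["state"].to_numpy()
    early_states = [s for s in config.states if s in ("RWC60", "RWC40", "RWC10")]

    for i, name in enumerate(names):
        fcs = {}
        if name in EARLY_SHOOT_METABOLITES:
            for s in early_states:
                mean[i, (tissue == "shoot") & (state == s)] *= 4.0
                fcs[("shoot", s)] = 4.0
        if name in LATE_ROOT_METABOLITES:
            if "RWC10" in config.states:
                mean[i, (tissue == "root") & (state == "RWC10")] *= 4.0
                fcs[("root", "RWC10")] = 4.0
            if "rehydrated" in config.states:
                mean[i, (tissue == "root") & (state == "rehydrated")] *= 2.0
                fcs[("root", "rehydrated")] = 2.0
        if fcs:
            truth_fc[name] = fcs

    # lognormal with sigma=0.10 => ~10% multiplicative noise, typical of
    # replicated GC-MS panels
    noise = rng.normal(0.0, 0.10, size=mean.shape)
    mat = mean * np.exp(noise)
    met = pd.DataFrame(mat, index=pd.Index(names, name="metabolite"),
                       columns=samples["sample_id"].to_numpy())
    truth = SyntheticTruth(metabolite_truth=truth_fc)
    return met, samples, truth


#: Population state means (pmol/mg) for the three hormones. ABA is
#: highest in hydrated/mildly dehydrated tissue; SA accumulates from
#: 60% RWC and keeps rising; JA-Ile declines from 60% RWC onward.
HORMONE_MEANS = {
    "ABA": {"hydrated": 100.0, "RWC80": 90.0, "RWC60": 40.0,
            "RWC40": 30.0, "RWC10": 25.0, "rehydrated": 35.0},
    "SA": {"hydrated": 10.0, "RWC80": 12.0, "RWC60": 30.0,
           "RWC40": 45.0, "RWC10": 60.0, "rehydrated": 50.0},
    "JA-Ile": {"hydrated": 20.0, "RWC80": 19.0, "RWC60": 12.0,
               "RWC40": 6.0, "RWC10": 4.0, "rehydrated": 5.0},
}


def generate_hormones(config: SimulationConfig, noise_sd: float = 2.0):
    """Simulate long-format phytohormone measurements.

    Returns a DataFrame with columns (hormone, state, replicate,
    conc_pmol_per_mg) plus a :class:`SyntheticTruth` holding the
    population state-mean profile of each hormone. Concentrations are
    clipped at zero.
    """
    rng = _rng(config.seed, "hormones")
    rows = []
    truth = SyntheticTruth()
    for hormone in HORMONES:
        profile = {s: HORMONE_MEANS[hormone][s]
                   for s in config.states if s in HORMONE_MEANS[hormone]}
        truth.hormone_profile_truth[hormone] = profile
        for s, mu in profile.items():
            vals = np.clip(rng.normal(mu, noise_sd, size=config.replicates), 0, None)
            for r, v in enumerate(vals, start=1):
                rows.append({"hormone": hormone, "state": s, "replicate": r,
                             "conc_pmol_per_mg": float(v)})
    return pd.DataFrame(rows), truth


def generate_physiology(config: SimulationConfig, n_plants: int = 5):
    """Simulate the drying-experiment records.

    Returns
    -------
    weights : pandas.DataFrame
        fresh/dry/turgid weight triples whose computed RWC falls inside
        the declared band (sampled away from the band edges).
    viability : pandas.DataFrame
        Evans Blue A600 readings per treatment, with boiled-positive
        and hydrated-negative controls. Rapidly dried plants that had
        not acclimated (bands >= 80% RWC) read high; plants gradually
        dried to 60% RWC or below read low.
    survival : pandas.DataFrame
        resurrection counts per pre-drying band: 0/5 for the hydrated
        control and the 100-80 band, 5/5 for 70-60 and drier.
    """
    rng = _rng(config.seed, "physiology")

    w_rows = []
    for band in RWC_BANDS:
        lo, hi = BAND_BOUNDS[band]
        margin = 0.05 * (hi - lo)
        for r in range(1, config.replicates + 1):
            target = rng.uniform(lo + margin, hi - margin)
            dw = rng.uniform(0.5, 1.5)
            tw = dw + rng.uniform(1.0, 2.0)
            fw = dw + (target / 100.0) * (tw - dw)
            w_rows.append({"sample_id": f"{band}_r{r}", "rwc_band": band,
                           "fresh_weight": fw, "dry_weight": dw,
                           "turgid_weight": tw})
    weights = pd.DataFrame(w_rows)

    # A600 population means: membrane damage is high when rapid drying hit
    # unacclimated tissue, low once tolerance was induced (<= 60% RWC).
    a600_means = {"boiled-positive": 1.2, "hydrated-negative": 0.10,
                  "100-80": 1.00, "70-60": 0.30, "50-40": 0.28,
                  "30-20": 0.26, "<10": 0.25}
    v_rows = []
    for treatment, mu in a600_means.items():
        for r in range(1, config.replicates + 1):
            a = max(0.0, rng.normal(mu, 0.03))
            v_rows.append({"sample_id": f"{treatment}_r{r}",
                           "treatment": treatment, "a600": a})
    viability = pd.DataFrame(v_rows)

    surv_rows = [{"rwc_band": "hydrated-control", "n_plants": n_plants,
                  "n_resurrected": 0}]
    for band in RWC_BANDS:
        ok = band not in ("100-80",)
        surv_rows.append({"rwc_band": band, "n_plants": n_plants,
                          "n_resurrected": n_plants if ok else 0})
    survival = pd.DataFrame(surv_rows)

    return weights, viability, survival
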