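"""Synthetic two-color microarray experiments with known per-gene truth.

The generator emulates the statistical structure the downstream analysis
assumes: log-normally distributed baseline expression, genes with true sex
effects whose onset is 3, 4 or 8 wk, developmental up/down trajectories,
redundant probes sharing a gene symbol, additive + multiplicative
(Rocke-Durbin form) intensity noise, an intensity-dependent dye bias that
is removable by LOWESS normalization, and dye-swapped replicate pairs.

Expression truth is anchored at the adult (8 wk) time point:

* the female trajectory is flat from 3 to 4 wk, with the 8-wk level moved
  by ``effect_fold`` when ``dev_change_female`` is up or down;
* sex-specific genes multiply the male level by ``effect_fold`` (male-
  specific) or divide it (female-specific) at every age at or past the
  onset age, so the male developmental change is *derived* from this
  construction rather than sampled independently (the two are not free
  simultaneously);
* sex-independent genes get independently sampled per-sex trajectories
  that meet at 8 wk; discordant ones therefore show a real transient
  early sex-bias, as seen for a minority of adult sex-independent genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from liverdev.design import COMPARISONS, CONDITIONS, ExperimentDesign

MALE = "male-specific"
FEMALE = "female-specific"
SEX_INDEP = "sex-independent"

#: Default class mix: roughly one adult sex-specific gene in five, split
#: evenly between the sexes, as in adult mouse liver.
DEFAULT_CLASS_PROPORTIONS = {MALE: 0.10, FEMALE: 0.11, SEX_INDEP: 0.79}

#: Onset-age mix among sex-specific genes: the large majority of adult
#: sex differences first appear at 8 wk, a minority by 4 wk, very few by 3 wk.
DEFAULT_ONSET_PROBS = {"3wk": 0.015, "4wk": 0.13, "8wk": 0.855}

#: Developmental-change mix; male liver shows more post-pubertal changes
#: than female liver.
DEFAULT_DEV_PROBS_MALE = {"up": 0.25, "down": 0.30, "none": 0.45}
DEFAULT_DEV_PROBS_FEMALE = {"up": 0.20, "down": 0.25, "none": 0.55}


@dataclass
class TruthRecord:
    """Ground truth for one gene.

    ``dev_change_male``/``dev_change_female`` describe the direction of the
    true 3->8 and 4->8 wk changes; ``mixed`` marks the (rare) case where
    the two intervals move in opposite directions in that sex.
    """

    gene_id: str
    true_class: str
    onset_age: str  # "3wk" | "4wk" | "8wk" | "none"
    dev_change_male: str  # "up" | "down" | "none" | "mixed"
    dev_change_female: str
    base_level: float
    effect_fold: float

    def __post_init__(self) -> None:
        if self.true_class not in (MALE, FEMALE, SEX_INDEP):
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if (self.onset_age == "none") != (self.true_class == SEX_INDEP):
            raise ValueError("onset_age is 'none' iff the gene is sex-independent")
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")


@dataclass
class NoiseParams:
    """Measurement-noise settings for simulated arrays (linear intensity units).

    sigma_add
        SD of the additive background noise component.
    sigma_mult
        Coefficient of variation of the multiplicative (log-normal) component.
    dye_bias_amplitude
        Peak-to-center magnitude (log2 scale) of the smooth intensity-
        dependent dye bias; applied with opposite sign to the two channels.
    background_mean, background_sd
        Background population of the array.
    frac_low_expressed
        Fraction of probes whose true level sits at background, so they
        fail the well-above-background filter.
    """

    sigma_add: float = 5.0
    sigma_mult: float = 0.1
    dye_bias_amplitude: float = 0.3
    background_mean: float = 20.0
    background_sd: float = 4.0
    frac_low_expressed: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma_add", "sigma_mult", "dye_bias_amplitude",
                     "background_mean", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.frac_low_expressed <= 1:
            raise ValueError("frac_low_expressed must be in [0, 1]")


def _dev_factor(change: str, effect: float) -> float:
    """Linear 8wk/3wk ratio implied by a developmental change label."""
    if change == "up":
        return effect
    if change == "down":
        return 1.0 / effect
    return 1.0


def _direction(ratio: float, tol: float = 1e-9) -> str:
    if ratio > 1 + tol:
        return "up"
    if ratio < 1 - tol:
        return "down"
    return "none"


def _derive_dev(r38: float, r48: float) -> str:
    dirs = {_direction(r) for r in (r38, r48)} - {"none"}
    if not dirs:
        return "none"
    if len(dirs) == 2:
        return "mixed"
    return dirs.pop()


def _gene_levels(rec: TruthRecord) -> dict[str, float]:
    """Six true linear levels (M3, M4, M8, F3, F4, F8) for one gene.

    Ratios between cells are fully determined by the record; the overall
    scale is anchored so that the geometric mean of the six cells equals
    ``base_level``.  Centering each gene this way keeps the mean intensity
    of a comparison essentially uncorrelated with that comparison's own
    log ratio across the gene population, so real regulation does not
    masquerade as an intensity-dependent dye trend during normalization
    (an anchoring that pins one fixed age instead induces exactly such a
    correlation).
    """
    b, e = rec.base_level, rec.effect_fold
    if rec.true_class == SEX_INDEP:
        f8 = m8 = b
        f3 = f4 = b / _dev_factor(rec.dev_change_female, e)
        m3 = m4 = b / _dev_factor(rec.dev_change_male, e)
    else:
        f8 = b
        f3 = f4 = b / _dev_factor(rec.dev_change_female, e)
        onset_rank = {"3wk": 0, "4wk": 1, "8wk": 2}[rec.onset_age]
        sex_fold = e if rec.true_class == MALE else 1.0 / e
        s = [sex_fold if age >= onset_rank else 1.0 for age in range(3)]
        m3, m4, m8 = s[0] * f3, s[1] * f4, s[2] * f8
    cells = np.array([m3, m4, m8, f3, f4, f8], dtype=float)
    cells *= b / np.exp(np.log(cells).mean())
    m3, m4, m8, f3, f4, f8 = cells
    return {"M3": m3, "M4": m4, "M8": m8, "F3": f3, "F4": f4, "F8": f8}


def generate_truth(
    n_genes: int,
    class_proportions: dict[str, float] | None = None,
    effect_fold_range: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
    *,
    onset_probs: dict[str, float] | None = None,
    dev_probs_male: dict[str, float] | None = None,
    dev_probs_female: dict[str, float] | None = None,
    base_level_median: float = 1000.0,
    base_level_sigma: float = 1.6,
    base_level_floor: float = 200.0,
) -> list[TruthRecord]:
    """Sample ``n_genes`` ground-truth records.

    Deterministic given ``seed``.  ``class_proportions`` must sum to 1;
    ``effect_fold_range`` must lie in [1, inf).  For sex-specific genes the
    male developmental change is derived from the anchored trajectory
    construction (see module docstring), keeping all record invariants
    mutually satisfiable.

    Baseline levels are log-normal (``base_level_sigma`` in natural-log
    units, so the default spans several orders of magnitude as on a real
    array), left-truncated at ``base_level_floor``: truth records describe
    *expressed* genes, while probes at background level are modeled
    separately through ``NoiseParams.frac_low_expressed``.
    """
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None
                 else class_proportions)
    for cls in (MALE, FEMALE, SEX_INDEP):
        props.setdefault(cls, 0.0)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"class proportions must sum to 1 (got {total})")
    lo, hi = effect_fold_range
    if lo < 1 or hi < lo:
        raise ValueError("effect_fold_range must be an interval within [1, inf)")
    onset_probs = dict(DEFAULT_ONSET_PROBS if onset_probs is None else onset_probs)
    dev_m = dict(DEFAULT_DEV_PROBS_MALE if dev_probs_male is None else dev_probs_male)
    dev_f = dict(DEFAULT_DEV_PROBS_FEMALE if dev_probs_female is None
                 else dev_probs_female)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    classes = rng.choice(
        [MALE, FEMALE, SEX_INDEP], size=n_genes,
        p=[props[MALE], props[FEMALE], props[SEX_INDEP]],
    )
    effects = rng.uniform(lo, hi, size=n_genes)
    if base_level_floor >= base_level_median:
        raise ValueError("base_level_floor must be below base_level_median")
    trunc_a = np.log(base_level_floor / base_level_median) / base_level_sigma
    bases = base_level_median * np.exp(stats.truncnorm.rvs(
        trunc_a, np.inf, scale=base_level_sigma, size=n_genes, random_state=rng,
    ))
    onset_keys = list(onset_probs)
    onsets = rng.choice(onset_keys, size=n_genes,
                        p=[onset_probs[k] for k in onset_keys])
    devm_keys, devf_keys = list(dev_m), list(dev_f)
    devms = rng.choice(devm_keys, size=n_genes, p=[dev_m[k] for k in devm_keys])
    devfs = rng.choice(devf_keys, size=n_genes, p=[dev_f[k] for k in devf_keys])

    records = []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        cls = str(classes[i])
        onset = "none" if cls == SEX_INDEP else str(onsets[i])
        rec = TruthRecord(
            gene_id=f"G{i:0{width}d}",
            true_class=cls,
            onset_age=onset,
            dev_change_male=str(devms[i]),
            dev_change_female=str(devfs[i]),
            base_level=float(bases[i]),
            effect_fold=float(effects[i]),
        )
        if cls != SEX_INDEP:
            # Male trajectory is determined by the construction; store the
            # implied developmental direction.
            lv = _gene_levels(rec)
            rec.dev_change_male = _derive_dev(lv["M8"] / lv["M3"],
                                              lv["M8"] / lv["M4"])
        records.append(rec)
    return records


def expression_matrix(truth: list[TruthRecord]) -> pd.DataFrame:
    """True linear expression per gene (rows) x condition (columns).

    The cell ratios realize each record's declared class, onset and
    developmental changes exactly; a record whose declared male change
    contradicts the anchored construction raises ``ValueError``.
    """
    rows = {}
    for rec in truth:
        lv = _gene_levels(rec)
        derived = _derive_dev(lv["M8"] / lv["M3"], lv["M8"] / lv["M4"])
        if rec.true_class != SEX_INDEP and derived != rec.dev_change_male:
            raise ValueError(
                f"{rec.gene_id}: declared dev_change_male={rec.dev_change_male!r} "
                f"is inconsistent with class/onset/dev_change_female "
                f"(implied {derived!r})"
            )
        rows[rec.gene_id] = [lv[c] for c in CONDITIONS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONDITIONS))


@dataclass
class ArrayData:
    """One simulated array: metadata plus its probe-level table."""

    comparison_id: str
    replicate: int
    swapped: bool  # dye-swapped: canonical numerator sample in the green channel
    red_sample: str
    green_sample: str
    table: pd.DataFrame  # probe_id, gene_symbol, red_raw, green_raw, bg_mean, bg_sd


def probe_layout(truth: list[TruthRecord], design: ExperimentDesign) -> pd.DataFrame:
    """Probe -> gene assignment; the first ``n_redundant_genes`` genes get
    two probes each, every other gene one."""
    if len(truth) != design.n_genes:
        raise ValueError(
            f"truth has {len(truth)} genes but design expects {design.n_genes}"
        )
    gene_ids = [rec.gene_id for rec in truth]
    symbols = gene_ids[: design.n_redundant_genes] + gene_ids
    probe_ids = [f"P{i:06d}" for i in range(len(symbols))]
    return pd.DataFrame({"probe_id": probe_ids, "gene_symbol": symbols})


def low_expressed_probes(design: ExperimentDesign, noise: NoiseParams) -> np.ndarray:
    """Boolean mask of probes whose true signal sits at background level.

    A property of the probe set (chosen once per design seed, shared by
    every array), so it is reproducible alongside the simulated arrays.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(10_000,))
    )
    n_low = int(np.floor(noise.frac_low_expressed * design.n_probes))
    mask = np.zeros(design.n_probes, dtype=bool)
    if n_low:
        mask[rng.choice(design.n_probes, size=n_low, replace=False)] = True
    return mask


def _dye_bias(a: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth intensity-dependent dye bias (log2 units) as a function of A."""
    return amplitude * np.cos(np.pi * (a - 8.0) / 6.0)


def simulate_arrays(
    truth: list[TruthRecord],
    design: ExperimentDesign,
    noise: NoiseParams,
) -> list[ArrayData]:
    """Simulate every array of the design.

    Each observed channel intensity is
    ``true_level * exp(N(0, sigma_mult^2)) + N(0, sigma_add^2)`` truncated
    at zero, after a dye bias (a smooth function of the probe's noiseless
    mean log2 intensity) has been applied with opposite sign to the two
    channels.  Odd replicates are dye swaps.  Each array draws from its own
    RNG stream sub-seeded from ``design.seed``, so adding arrays never
    perturbs earlier ones.
    """
    layout = probe_layout(truth, design)
    expr = expression_matrix(truth)
    per_probe = expr.loc[layout["gene_symbol"]].to_numpy()  # n_probes x 6
    cond_ix = {c: i for i, c in enumerate(CONDITIONS)}

    low_mask = low_expressed_probes(design, noise)

    arrays: list[ArrayData] = []
    for array_idx, (cid, rep, swapped) in enumerate(design.arrays):
        num, den = COMPARISONS[cid]
        red_sample, green_sample = (den, num) if swapped else (num, den)
        t_red = per_probe[:, cond_ix[red_sample]].copy()
        t_green = per_probe[:, cond_ix[green_sample]].copy()
        t_red[low_mask] = 0.5 * noise.background_mean
        t_green[low_mask] = 0.5 * noise.background_mean

        with np.errstate(divide="ignore"):
            a0 = 0.5 * (np.log2(np.maximum(t_red, 1e-12))
                        + np.log2(np.maximum(t_green, 1e-12)))
        bias = _dye_bias(a0, noise.dye_bias_amplitude)
        t_red = t_red * 2.0 ** (0.5 * bias)
        t_green = t_green * 2.0 ** (-0.5 * bias)

        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=design.seed, spawn_key=(array_idx,))
        )
        n = design.n_probes
        red = t_red * np.exp(rng.normal(0.0, noise.sigma_mult, n)) \
            + rng.normal(0.0, noise.sigma_add, n)
        green = t_green * np.exp(rng.normal(0.0, noise.sigma_mult, n)) \
            + rng.normal(0.0, noise.sigma_add, n)
        bg_mean = np.maximum(
            rng.normal(noise.background_mean, noise.background_sd, n), 0.0
        )
        table = pd.DataFrame({
            "probe_id": layout["probe_id"],
            "gene_symbol": layout["gene_symbol"],
            "red_raw": np.maximum(red, 0.0),
            "green_raw": np.maximum(green, 0.0),
            "bg_mean": bg_mean,
            "bg_sd": np.full(n, noise.background_sd),
        })
        arrays.append(ArrayData(cid, rep, swapped, red_sample, green_sample, table))
    return arrays


def write_simulation(
    arrays: list[ArrayData],
    truth: list[TruthRecord],
    outdir: str | Path,
) -> pd.DataFrame:
    """Write per-array TSVs, the design manifest and the truth table.

    Returns the manifest frame (comparison id, replicate, dye orientation,
    file name).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for arr in arrays:
        fname = f"array_{arr.comparison_id}_rep{arr.replicate}.tsv"
        arr.table.to_csv(outdir / fname, sep="\t", index=False, float_format="%.6g")
        rows.append({
            "comparison_id": arr.comparison_id,
            "replicate": arr.replicate,
            "dye_swapped": int(arr.swapped),
            "red_sample": arr.red_sample,
            "green_sample": arr.green_sample,
            "file": fname,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "design_manifest.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame([{
        "gene_id": r.gene_id,
        "true_class": r.true_class,
        "onset_age": r.onset_age,
        "dev_change_male": r.dev_change_male,
        "dev_change_female": r.dev_change_female,
        "effect_fold": r.effect_fold,
        "base_level": r.base_level,
    } for r in truth])
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    return manifest
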