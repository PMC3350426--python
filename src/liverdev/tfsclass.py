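"""Ternary flag (TFS) encoding and gene classification.

Every gene's regulation pattern across the seven comparisons is encoded as
seven ternary flags: 0 = not significantly changed, 1 = up-regulated
(ratio > fold_cut with p < p_cut on a well-above-background probe),
2 = down-regulated (ratio < 1/fold_cut).  The flags read, in order:
sex bias at 3, 4 and 8 wk (up = male-biased), then developmental change
3->8 and 4->8 wk in male liver and 3->8 and 4->8 wk in female liver
(up = rises with age).  A binary-weighted whole number (weights 1, 2, 4,
8, 16, 32, 64 for positions 1-7, counting any nonzero flag) summarizes
which comparisons fired, and the decimal rendering "W.f1f2f3f4f5f6f7"
carries the full pattern; e.g. flags (0,0,2,2,2,0,0) encode as 28.0022200:
female-specific at 8 wk, down-regulated with age in male liver.

Classification derives from the flags alone: adult sex class from the 8-wk
sex comparison; onset as the earliest age whose sex flag agrees in
direction with the 8-wk call; opposite-direction or 8-wk-absent early sex
bias is recorded separately as a transient bias; developmental calls per
sex from the two interval flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from liverdev.design import ADULT_SEX_INDEX, COMPARISON_IDS

TFS_WEIGHTS = (1, 2, 4, 8, 16, 32, 64)


@dataclass
class Thresholds:
    """Significance and filter thresholds (ratios linear, intensities in
    linear array units)."""

    fold_cut: float = 1.5
    p_cut: float = 1e-4
    stringent_fold: float = 1.2
    stringent_p: float = 0.01
    min_intensity: float = 25.0
    regulator_fold: float = 2.0
    regulator_sex_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.fold_cut <= 1:
            raise ValueError("fold_cut must exceed 1")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if self.stringent_fold >= self.fold_cut:
            raise ValueError("stringent_fold must be below fold_cut")
        if self.stringent_p <= self.p_cut:
            raise ValueError("stringent_p must exceed p_cut")


@dataclass
class TFSCode:
    flags: tuple
    whole: int = field(init=False)
    decimal_string: str = field(init=False)

    def __post_init__(self) -> None:
        flags = tuple(int(f) for f in self.flags)
        if len(flags) != 7 or any(f not in (0, 1, 2) for f in flags):
            raise ValueError("flags must be seven values in {0, 1, 2}")
        self.flags = flags
        self.whole = sum(w for w, f in zip(TFS_WEIGHTS, flags) if f != 0)
        self.decimal_string = f"{self.whole}." + "".join(str(f) for f in flags)


def encode_tfs(flags) -> TFSCode:
    """Encode a 7-vector of ternary flags as a TFS code."""
    return TFSCode(tuple(flags))


def decode_tfs(decimal_string: str) -> tuple:
    """Recover the flag vector from a "W.f1f2f3f4f5f6f7" rendering."""
    try:
        whole_part, frac = decimal_string.strip().split(".")
        flags = tuple(int(c) for c in frac)
        whole = int(whole_part)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed TFS string: {decimal_string!r}") from exc
    code = TFSCode(flags)
    if code.whole != whole:
        raise ValueError(
            f"inconsistent TFS string {decimal_string!r}: "
            f"flags imply whole number {code.whole}"
        )
    return code.flags


def flag_comparison(ratio: float, p_value: float, wab: bool,
                    th: Thresholds | None = None) -> int:
    """Ternary flag for one gene in one comparison (``ratio`` is linear).

    1 = up (ratio > fold_cut), 2 = down (ratio < 1/fold_cut), both
    requiring p < p_cut and the well-above-background condition; strict
    inequalities throughout, so a ratio of exactly fold_cut is unflagged.
    """
    th = th or Thresholds()
    if not wab or not np.isfinite(ratio) or not np.isfinite(p_value):
        return 0
    if p_value >= th.p_cut:
        return 0
    if ratio > th.fold_cut:
        return 1
    if ratio < 1.0 / th.fold_cut:
        return 2
    return 0


def flag_array(log2_ratio: np.ndarray, p_value: np.ndarray, wab: np.ndarray,
               th: Thresholds | None = None) -> np.ndarray:
    """Vectorized ``flag_comparison`` on log2 ratios."""
    th = th or Thresholds()
    log2_ratio = np.asarray(log2_ratio, dtype=float)
    p_value = np.asarray(p_value, dtype=float)
    ok = (np.asarray(wab, dtype=bool) & np.isfinite(log2_ratio)
          & np.isfinite(p_value) & (p_value < th.p_cut))
    cut = np.log2(th.fold_cut)
    flags = np.zeros(log2_ratio.shape, dtype=int)
    flags[ok & (log2_ratio > cut)] = 1
    flags[ok & (log2_ratio < -cut)] = 2
    return flags


def probe_table(summaries: dict[str, pd.DataFrame],
                th: Thresholds | None = None) -> pd.DataFrame:
    """Merge the seven per-comparison summaries into one wide per-probe frame.

    Emits, for comparison i (1-based, canonical order): ``flag_i``,
    ``ratio_i`` (log2), ``p_i``, ``int_i``, ``wab_i``; plus the TFS whole
    number and decimal string per probe.
    """
    th = th or Thresholds()
    missing = [c for c in COMPARISON_IDS if c not in summaries]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    base = summaries[COMPARISON_IDS[0]][["gene_id", "probe_id"]].copy()
    flags = np.zeros((len(base), 7), dtype=int)
    for i, cid in enumerate(COMPARISON_IDS, start=1):
        s = summaries[cid]
        if not s["probe_id"].reset_index(drop=True).equals(
                base["probe_id"].reset_index(drop=True)):
            raise ValueError(f"probe layout of {cid} differs from {COMPARISON_IDS[0]}")
        flags[:, i - 1] = flag_array(s["log2_ratio"], s["p_value"], s["wab"], th)
        base[f"flag_{i}"] = flags[:, i - 1]
        base[f"ratio_{i}"] = s["log2_ratio"].to_numpy()
        base[f"p_{i}"] = s["p_value"].to_numpy()
        base[f"int_{i}"] = s["intensity"].to_numpy()
        base[f"wab_{i}"] = s["wab"].to_numpy()
    nonzero = flags != 0
    base["tfs_whole"] = (nonzero * np.array(TFS_WEIGHTS)).sum(axis=1)
    base["tfs_decimal"] = [
        f"{w}." + "".join(map(str, row))
        for w, row in zip(base["tfs_whole"], flags)
    ]
    return base


def remove_redundant_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse probes sharing gene symbol *and* TFS group to one probe.

    Within each (gene, TFS) group the surviving probe minimizes the sum of
    log10 p over the comparisons where its flag is nonzero ("lowest set of
    p-values"); ties break to the lexicographically smallest probe id.
    Probes of the same gene in different TFS groups are all retained.
    """
    flag_cols = [f"flag_{i}" for i in range(1, 8)]
    p_cols = [f"p_{i}" for i in range(1, 8)]
    flags = probes[flag_cols].to_numpy()
    logp = np.log10(np.clip(probes[p_cols].to_numpy(dtype=float), 1e-300, None))
    score = np.where(flags != 0, logp, 0.0).sum(axis=1)
    work = probes.assign(_score=score)
    work = work.sort_values(["_score", "probe_id"], kind="mergesort")
    kept = work.drop_duplicates(subset=["gene_id", "tfs_decimal"], keep="first")
    return (kept.drop(columns="_score")
                .sort_values("probe_id", kind="mergesort")
                .reset_index(drop=True))


@dataclass
class GeneClassification:
    sex_class: str  # male-specific | female-specific | sex-independent
    onset: str  # 3wk | 4wk | 8wk | n/a
    transient_bias: str  # M-at-3wk | F-at-3wk | M-at-4wk | F-at-4wk | none
    dev_male: str  # up | down | mixed | none
    dev_female: str
    dev_male_38: str  # U | D | NC
    dev_male_48: str
    dev_female_38: str
    dev_female_48: str


_UDN = {0: "NC", 1: "U", 2: "D"}


def _dev_call(f_a: int, f_b: int) -> str:
    dirs = {f for f in (f_a, f_b) if f != 0}
    if not dirs:
        return "none"
    if len(dirs) == 2:
        return "mixed"
    return "up" if dirs.pop() == 1 else "down"


def classify_gene(tfs) -> GeneClassification:
    """Derive the full classification from a TFS code or 7-flag vector."""
    flags = tfs.flags if isinstance(tfs, TFSCode) else TFSCode(tuple(tfs)).flags
    adult = flags[ADULT_SEX_INDEX]
    sex_class = {0: "sex-independent", 1: "male-specific", 2: "female-specific"}[adult]

    onset = "n/a"
    if adult != 0:
        for flag, age in zip(flags[:3], ("3wk", "4wk", "8wk")):
            if flag == adult:
                onset = age
                break

    transient = "none"
    for flag, age in zip(flags[:2], ("3wk", "4wk")):
        if flag != 0 and flag != adult:
            transient = f"{'M' if flag == 1 else 'F'}-at-{age}"
            break

    return GeneClassification(
        sex_class=sex_class,
        onset=onset,
        transient_bias=transient,
        dev_male=_dev_call(flags[3], flags[4]),
        dev_female=_dev_call(flags[5], flags[6]),
        dev_male_38=_UDN[flags[3]],
        dev_male_48=_UDN[flags[4]],
        dev_female_38=_UDN[flags[5]],
        dev_female_48=_UDN[flags[6]],
    )


def stringent_sex_independent(ratio: float, p_value: float, intensity: float,
                              th: Thresholds | None = None) -> bool:
    """Conservative sex-independence at 8 wk: sex ratio (either direction)
    below ``stringent_fold``, p above ``stringent_p``, intensity at least
    ``min_intensity``.  ``ratio`` is the linear 8-wk male/female ratio."""
    th = th or Thresholds()
    if not np.isfinite(ratio) or ratio <= 0 or not np.isfinite(p_value):
        return False
    return (max(ratio, 1.0 / ratio) < th.stringent_fold
            and p_value > th.stringent_p
            and intensity >= th.min_intensity)


def classify_table(probes: pd.DataFrame,
                   th: Thresholds | None = None) -> pd.DataFrame:
    """Per-gene master classification from a deduplicated probe table.

    Genes appearing with several TFS groups keep one row per group (as in
    the source data); downstream summaries count rows.  Adds the
    ``regulated`` column (any nonzero flag) and the stringent
    sex-independence call based on the 8-wk sex comparison.
    """
    th = th or Thresholds()
    flag_cols = [f"flag_{i}" for i in range(1, 8)]
    rows = []
    for _, r in probes.iterrows():
        flags = tuple(int(r[c]) for c in flag_cols)
        cls = classify_gene(flags)
        adult_i = ADULT_SEX_INDEX + 1
        ratio8 = float(2.0 ** r[f"ratio_{adult_i}"]) \
            if np.isfinite(r[f"ratio_{adult_i}"]) else np.nan
        stringent = (cls.sex_class == "sex-independent") and stringent_sex_independent(
            ratio8, float(r[f"p_{adult_i}"]), float(r[f"int_{adult_i}"]), th
        )
        rows.append({
            "gene_id": r["gene_id"],
            "probe_id": r["probe_id"],
            "tfs_decimal": r["tfs_decimal"],
            "tfs_whole": int(r["tfs_whole"]),
            "regulated": int(r["tfs_whole"]) > 0,
            "sex_class": cls.sex_class,
            "onset": cls.onset,
            "transient_bias": cls.transient_bias,
            "dev_male": cls.dev_male,
            "dev_female": cls.dev_female,
            "dev_male_38": cls.dev_male_38,
            "dev_male_48": cls.dev_male_48,
            "dev_female_38": cls.dev_female_38,
            "dev_female_48": cls.dev_female_48,
            "stringent_SI": stringent,
        })
    return pd.DataFrame(rows)


def summarize_counts(master: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Count tables over the *regulated* genes of a master classification.

    Returns:

    - ``sex_by_onset``: sex class x onset age (plus transient early bias
      among adult sex-independent genes, tabulated separately);
    - ``dev_udn``: U/D/NC counts per sex class for each sex x interval;
    - ``change_location``: genes changing in male only / female only /
      both sexes / neither;
    - ``onset_conventions``: for each early age, genes with any
      same-direction bias at that age vs. those whose bias is retained at
      every later measured age.
    """
    reg = master[master["regulated"]]

    sex_by_onset = (reg.groupby(["sex_class", "onset"]).size()
                       .unstack(fill_value=0))
    transient = (reg.groupby(["sex_class", "transient_bias"]).size()
                    .unstack(fill_value=0))

    dev_frames = {}
    for col in ("dev_male_38", "dev_male_48", "dev_female_38", "dev_female_48"):
        dev_frames[col] = (reg.groupby(["sex_class", col]).size()
                              .unstack(fill_value=0))
    dev_udn = pd.concat(dev_frames, axis=1).fillna(0).astype(int)

    changed_m = reg["dev_male"] != "none"
    changed_f = reg["dev_female"] != "none"
    change_location = pd.DataFrame({
        "count": [
            int((changed_m & ~changed_f).sum()),
            int((~changed_m & changed_f).sum()),
            int((changed_m & changed_f).sum()),
            int((~changed_m & ~changed_f).sum()),
        ]
    }, index=["male_only", "female_only", "both", "neither"])

    sexed = reg[reg["sex_class"] != "sex-independent"]
    conventions = pd.DataFrame({
        "any_bias": [
            int((sexed["onset"] == "3wk").sum() +
                sexed["transient_bias"].str.contains("3wk").sum()),
            int((sexed["onset"].isin(["3wk", "4wk"])).sum() +
                sexed["transient_bias"].str.contains("4wk").sum()),
        ],
        "same_direction_onset": [
            int((sexed["onset"] == "3wk").sum()),
            int((sexed["onset"].isin(["3wk", "4wk"])).sum()),
        ],
    }, index=["3wk", "4wk"])

    return {
        "sex_by_onset": sex_by_onset,
        "transient": transient,
        "dev_udn": dev_udn,
        "change_location": change_location,
        "onset_conventions": conventions,
    }


def filter_candidate_regulators(
    probes: pd.DataFrame,
    master: pd.DataFrame,
    annotations: pd.DataFrame,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Candidate transcriptional regulators among the regulated genes.

    Keeps genes whose GO descriptor contains "DNA binding" or
    "transcription" (case-insensitive), with 8-wk signal intensity of at
    least ``min_intensity``, an absolute fold change above
    ``regulator_fold`` on every comparison where p < p_cut, and — for
    adult sex-biased genes — an 8-wk sex ratio above ``regulator_sex_fold``
    (or below its reciprocal).  ``annotations`` has columns gene_id,
    descriptor.
    """
    th = th or Thresholds()
    desc = annotations.set_index(
        annotations["gene_id"].str.casefold())["descriptor"].astype(str)
    merged = probes.merge(
        master[["probe_id", "sex_class", "regulated"]], on="probe_id")
    merged = merged[merged["regulated"]]

    keep = []
    adult_i = ADULT_SEX_INDEX + 1
    cut = np.log2(th.regulator_fold)
    sex_cut = np.log2(th.regulator_sex_fold)
    for _, r in merged.iterrows():
        text = desc.get(str(r["gene_id"]).casefold(), "")
        low = text.casefold()
        if "dna binding" not in low and "transcription" not in low:
            continue
        if r[f"int_{adult_i}"] < th.min_intensity:
            continue
        ok = True
        for i in range(1, 8):
            p = r[f"p_{i}"]
            if np.isfinite(p) and p < th.p_cut and \
                    abs(r[f"ratio_{i}"]) <= cut:
                ok = False
                break
        if not ok:
            continue
        if r["sex_class"] != "sex-independent" and \
                abs(r[f"ratio_{adult_i}"]) <= sex_cut:
            continue
        keep.append({"gene_id": r["gene_id"], "probe_id": r["probe_id"],
                     "sex_class": r["sex_class"], "descriptor": text})
    return pd.DataFrame(keep, columns=["gene_id", "probe_id", "sex_class",
                                       "descriptor"])
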