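"""Protein- and Kcr-site-level differential quantification.

Implements the reporter-ion workflow of a 6-plex TMT comparison (3 control
vs 3 treatment channels): per-channel mean normalization, protein ratios as
the median over unique-peptide T/CK ratios, two-sample two-tailed t-tests
on log2 intensities, fold-change/p-value regulation classes, proteome
normalization of site ratios (site ratio divided by the parent protein's
ratio), and joint protein/PTM crosstalk classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ChannelDesign, ProteinRecord

log = logging.getLogger(__name__)

UP, DOWN, UNCHANGED, UNQUANTIFIED = "up", "down", "unchanged", "unquantified"


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds of the quantification workflow.

    ``fc_threshold`` — fold-change cutoff (up if ratio > fc, down if
    ratio < 1/fc). ``alpha`` — p-value cutoff paired with the ratio rule
    when ``use_pvalue`` is set. ``loc_prob_min`` — sites at or below this
    localization probability are dropped. ``min_values_per_group`` — a
    peptide/site contributes to a group mean only with at least this many
    non-missing channel values per group. ``welch`` — unequal-variance
    t-test (default) vs pooled.
    """

    fc_threshold: float = 1.2
    alpha: float = 0.05
    loc_prob_min: float = 0.75
    min_values_per_group: int = 2
    use_pvalue: bool = True
    welch: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.loc_prob_min <= 1:
            raise ValueError("loc_prob_min must lie in [0, 1]")


@dataclass
class ProteinResult:
    protein_id: str
    ratio: float | None
    log2_ratio: float | None
    p_value: float | None
    n_unique_peptides: int
    reg_class: str


@dataclass
class SiteResult:
    protein_id: str
    position: int
    raw_ratio: float | None
    norm_ratio: float | None
    p_value: float | None
    reg_class: str
    normalized: bool  # False when the parent protein was unquantified


@dataclass
class CrosstalkRecord:
    protein_id: str
    protein_class: str
    site_class: str
    relation: str
    quadrant: int | None


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def mean_normalize(
    table: pd.DataFrame,
    design: ChannelDesign,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rescale each reporter channel to the pre-normalization grand mean.

    Each channel is multiplied by a single factor so that its mean over
    non-missing rows equals the grand mean of the per-channel means before
    normalization; missing cells stay missing. Centering the channel
    distributions this way removes channel loading differences while
    leaving within-row ratios between equally-scaled channels intact.

    Normalization is a peptide-level operation: when ``reference`` is given
    (typically the peptide table of the run), the per-channel factors are
    estimated on it and applied to ``table``. Use this for PTM-site tables,
    whose rows are dominated by the modification signal itself and would
    bias factors estimated in-table.
    """
    out = table.copy()
    ref = reference if reference is not None else table
    means = {}
    for ch in design.channel_labels:
        col = ref[ch].astype(float)
        if col.notna().sum() == 0:
            raise ValueError(f"channel {ch!r} has no non-missing values")
        means[ch] = float(col.mean())
    grand = float(np.mean(list(means.values())))
    for ch in design.channel_labels:
        out[ch] = out[ch].astype(float) * (grand / means[ch])
    return out


# ---------------------------------------------------------------------------
# Protein quantification
# ---------------------------------------------------------------------------

def _group_values(row: pd.Series, channels: list[str]) -> np.ndarray:
    vals = row[channels].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def _ttest_log2(t_vals: np.ndarray, ck_vals: np.ndarray, welch: bool) -> float | None:
    if len(t_vals) < 2 or len(ck_vals) < 2:
        return None
    res = stats.ttest_ind(np.log2(t_vals), np.log2(ck_vals), equal_var=not welch)
    p = float(res.pvalue)
    return None if math.isnan(p) else p


def _classify(ratio: float | None, p: float | None, config: QuantConfig) -> str:
    if ratio is None:
        return UNQUANTIFIED
    sig = True if not config.use_pvalue else (p is not None and p < config.alpha)
    if ratio > config.fc_threshold and sig:
        return UP
    if ratio < 1.0 / config.fc_threshold and sig:
        return DOWN
    return UNCHANGED


def quantify_proteins(
    peptide_table: pd.DataFrame,
    design: ChannelDesign,
    config: QuantConfig = QuantConfig(),
) -> list[ProteinResult]:
    """Quantify proteins from a mean-normalized peptide table.

    Per unique peptide the T/CK ratio is the ratio of group means over
    non-missing intensities (each group needing ``min_values_per_group``
    values); the protein ratio is the median of its unique-peptide ratios.
    The p-value comes from a two-sample two-tailed t-test on the log2
    per-channel protein intensities, where the protein intensity in a
    channel is the sum of its unique-peptide intensities there.
    """
    ck = design.channels("CK")
    t = design.channels("T")
    results = []
    for pid, sub in peptide_table.groupby("protein_id", sort=True):
        uniq = sub[sub["is_unique"].astype(int) == 1]
        ratios = []
        for _, row in uniq.iterrows():
            ck_vals = _group_values(row, ck)
            t_vals = _group_values(row, t)
            if (
                len(ck_vals) >= config.min_values_per_group
                and len(t_vals) >= config.min_values_per_group
            ):
                ratios.append(float(t_vals.mean() / ck_vals.mean()))
        if not ratios:
            results.append(ProteinResult(pid, None, None, None, 0, UNQUANTIFIED))
            continue
        ratio = float(np.median(ratios))
        ck_sums = uniq[ck].sum(axis=0, skipna=True).to_numpy(dtype=float)
        t_sums = uniq[t].sum(axis=0, skipna=True).to_numpy(dtype=float)
        ck_sums = ck_sums[ck_sums > 0]
        t_sums = t_sums[t_sums > 0]
        p = _ttest_log2(t_sums, ck_sums, config.welch)
        results.append(
            ProteinResult(
                pid, ratio, math.log2(ratio), p, len(ratios),
                _classify(ratio, p, config),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Site quantification with proteome normalization
# ---------------------------------------------------------------------------

def quantify_sites(
    site_table: pd.DataFrame,
    protein_results: list[ProteinResult],
    design: ChannelDesign,
    config: QuantConfig = QuantConfig(),
    proteins: list[ProteinRecord] | None = None,
) -> list[SiteResult]:
    """Quantify Kcr sites and normalize away protein-level change.

    Sites with localization probability <= ``loc_prob_min`` are excluded
    up front. Each surviving site is quantified like a single peptide
    (ratio of group means, t-test on log2 intensities). The normalized
    ratio divides the raw site ratio by the parent protein's ratio, so a
    site that merely tracks its protein's abundance comes out unchanged;
    when the parent is unquantified the site is classified on the raw
    ratio and flagged ``normalized=False``.
    """
    if proteins is not None:
        seqs = {p.protein_id: p.sequence for p in proteins}
        for _, row in site_table.iterrows():
            pid, pos = str(row["protein_id"]), int(row["position"])
            seq = seqs.get(pid)
            if seq is not None and (pos < 1 or pos > len(seq) or seq[pos - 1] != "K"):
                raise ValueError(
                    f"site position {pos} of protein {pid!r} is not a lysine"
                )
    prot_ratio = {
        r.protein_id: r.ratio for r in protein_results if r.ratio is not None
    }
    ck = design.channels("CK")
    t = design.channels("T")
    kept = site_table[
        site_table["localization_prob"].astype(float) > config.loc_prob_min
    ]
    results = []
    for _, row in kept.iterrows():
        pid, pos = str(row["protein_id"]), int(row["position"])
        ck_vals = _group_values(row, ck)
        t_vals = _group_values(row, t)
        if (
            len(ck_vals) < config.min_values_per_group
            or len(t_vals) < config.min_values_per_group
        ):
            results.append(
                SiteResult(pid, pos, None, None, None, UNQUANTIFIED, False)
            )
            continue
        raw = float(t_vals.mean() / ck_vals.mean())
        p = _ttest_log2(t_vals, ck_vals, config.welch)
        parent = prot_ratio.get(pid)
        if parent is not None:
            norm = raw / parent
            results.append(
                SiteResult(pid, pos, raw, norm, p, _classify(norm, p, config), True)
            )
        else:
            results.append(
                SiteResult(pid, pos, raw, None, p, _classify(raw, p, config), False)
            )
    return results


# ---------------------------------------------------------------------------
# Protein / PTM crosstalk
# ---------------------------------------------------------------------------

_SIGN = {UP: 1, DOWN: -1}


def crosstalk(
    protein_results: list[ProteinResult],
    site_results: list[SiteResult],
) -> tuple[list[CrosstalkRecord], dict[str, int]]:
    """Classify joint protein/site regulation per protein.

    ``consistent`` — protein and at least one site share a non-unchanged
    class with no site contradicting; ``opposite`` — protein and site
    classes are both non-unchanged with discordant signs; ``mixed`` —
    sites of a differential protein go both ways; ``unchanged`` — both
    datasets cover the protein but neither call is differential;
    ``protein_only`` / ``site_only`` — quantified on one side only. The
    quadrant places (protein log2 ratio, mean site normalized log2 ratio):
    1 = (+,+), 2 = (−,+), 3 = (−,−), 4 = (+,−).
    """
    prot = {r.protein_id: r for r in protein_results if r.ratio is not None}
    sites_by_prot: dict[str, list[SiteResult]] = {}
    for s in site_results:
        if s.raw_ratio is not None:
            sites_by_prot.setdefault(s.protein_id, []).append(s)

    records = []
    counts = {
        "overlap": 0, "consistent": 0, "opposite": 0, "mixed": 0,
        "unchanged": 0, "protein_only": 0, "site_only": 0,
    }
    for pid in sorted(set(prot) | set(sites_by_prot)):
        p = prot.get(pid)
        ss = sites_by_prot.get(pid, [])
        if p is not None and not ss:
            records.append(
                CrosstalkRecord(pid, p.reg_class, UNQUANTIFIED, "protein_only", None)
            )
            counts["protein_only"] += 1
            continue
        if p is None:
            cls = _combined_site_class(ss)
            records.append(
                CrosstalkRecord(pid, UNQUANTIFIED, cls, "site_only", None)
            )
            counts["site_only"] += 1
            continue
        counts["overlap"] += 1
        site_cls = _combined_site_class(ss)
        site_signs = {_SIGN[s.reg_class] for s in ss if s.reg_class in _SIGN}
        p_sign = _SIGN.get(p.reg_class, 0)
        if p_sign != 0 and site_signs == {p_sign}:
            relation = "consistent"
        elif p_sign != 0 and site_signs == {-p_sign}:
            relation = "opposite"
        elif len(site_signs) > 1:
            relation = "mixed"
        elif p_sign != 0 and site_signs:
            relation = "mixed"
        else:
            relation = "unchanged"
        norm_l2 = [
            math.log2(s.norm_ratio) for s in ss if s.norm_ratio is not None
        ]
        quadrant = None
        if norm_l2 and p.log2_ratio is not None:
            x, y = p.log2_ratio, float(np.mean(norm_l2))
            quadrant = 1 if (x >= 0 and y >= 0) else 2 if (x < 0 and y >= 0) \
                else 3 if (x < 0 and y < 0) else 4
        records.append(CrosstalkRecord(pid, p.reg_class, site_cls, relation, quadrant))
        if relation in counts:
            counts[relation] += 1
    log.info("crosstalk summary: %s", counts)
    return records, counts


def _combined_site_class(sites: list[SiteResult]) -> str:
    signs = {_SIGN[s.reg_class] for s in sites if s.reg_class in _SIGN}
    if signs == {1}:
        return UP
    if signs == {-1}:
        return DOWN
    if len(signs) > 1:
        return "mixed"
    return UNCHANGED if sites else UNQUANTIFIED


# ---------------------------------------------------------------------------
# Frame converters for TSV output
# ---------------------------------------------------------------------------

def protein_results_frame(results: list[ProteinResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": r.protein_id, "ratio": r.ratio,
             "log2_ratio": r.log2_ratio, "p_value": r.p_value,
             "n_unique_peptides": r.n_unique_peptides, "reg_class": r.reg_class}
            for r in results
        ]
    )


def site_results_frame(results: list[SiteResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": r.protein_id, "position": r.position,
             "raw_ratio": r.raw_ratio, "norm_ratio": r.norm_ratio,
             "p_value": r.p_value, "reg_class": r.reg_class,
             "normalized": int(r.normalized)}
            for r in results
        ]
    )


def crosstalk_frame(records: list[CrosstalkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": r.protein_id, "protein_class": r.protein_class,
             "site_class": r.site_class, "relation": r.relation,
             "quadrant": r.quadrant}
            for r in records
        ]
    )
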