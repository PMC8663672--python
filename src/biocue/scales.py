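"""Scoring of self-report instruments and the study-style statistics.

Implements the System Usability Scale (SUS) 0–100 formula, generic
Likert-scale scoring with subscales, reverse keying and 80% proration, a
matched-pairs Wilcoxon signed-rank test (exact sign enumeration for small
samples, tie-corrected normal approximation otherwise), and product-moment
correlation.

The clinical instruments' item texts and item→subscale assignments are
copyrighted and not shipped; the bundled configurations for AQ-SF
(aggression questionnaire short form), STAXI-2 (state-trait anger
expression inventory) and ABSQ (anger bodily sensations questionnaire)
carry *synthetic placeholder mappings* — correct item counts, response
ranges and subscale names, but invented item assignments — and are meant
to be replaced with licensed mappings via YAML/JSON config.

Scores are item means on the native response scale (not sums), so a 1–5
instrument scores between 1 and 5.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

RESPONSE_COLUMNS = ["respondent_id", "timepoint", "instrument", "item_id", "response"]


# ---------------------------------------------------------------------------
# SUS

def sus_score(responses: Sequence[int]) -> float:
    """System Usability Scale overall score in [0, 100].

    ``responses`` are the ten item ratings in order, each 1–5, with the
    standard keying: odd items positively worded, even items negatively
    worded.  score = (sum_odd (r-1) + sum_even (5-r)) * 2.5.  No proration:
    a missing item is an error.
    """
    if len(responses) != 10:
        raise ValueError(f"SUS requires exactly 10 responses, got {len(responses)}")
    contributions = []
    for i, r in enumerate(responses, start=1):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            raise ValueError(f"SUS item {i} missing; SUS is not prorated")
        r = int(r)
        if not 1 <= r <= 5:
            raise ValueError(f"SUS item {i} response {r} outside [1, 5]")
        contributions.append(r - 1 if i % 2 == 1 else 5 - r)
    return sum(contributions) * 2.5


# ---------------------------------------------------------------------------
# Generic Likert scales

@dataclass(frozen=True)
class ScaleConfig:
    """Scoring configuration for one instrument.

    ``subscales`` maps subscale name → item ids (a partition of a subset of
    the items); ``reverse_items`` are reflected as r → max+min−r before
    aggregation.  ``aggregation`` is "mean" (item mean on the native scale)
    or "sus" (the SUS formula; items must be sus1..sus10).
    """

    name: str
    items: tuple[str, ...]
    response_min: int = 1
    response_max: int = 5
    subscales: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    reverse_items: frozenset = frozenset()
    aggregation: str = "mean"
    min_answered_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "sus"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        item_set = set(self.items)
        if not set(self.reverse_items) <= item_set:
            raise ValueError("reverse_items must be a subset of items")
        seen: set[str] = set()
        for sub, ids in self.subscales.items():
            ids_set = set(ids)
            if not ids_set <= item_set:
                raise ValueError(f"subscale {sub!r} references unknown items")
            if seen & ids_set:
                raise ValueError("subscales must not share items")
            seen |= ids_set

    @classmethod
    def from_file(cls, path: str | Path) -> "ScaleConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        d["items"] = tuple(d["items"])
        d["subscales"] = {k: tuple(v) for k, v in d.get("subscales", {}).items()}
        d["reverse_items"] = frozenset(d.get("reverse_items", ()))
        return cls(**d)


def _default_configs() -> dict[str, ScaleConfig]:
    # Synthetic placeholder mappings: real item->subscale assignments are
    # licensed content and must be supplied by the user.
    aq_items = tuple(f"aq{i}" for i in range(1, 13))
    staxi_items = tuple(
        [f"s{i}" for i in range(1, 6)] + [f"t{i}" for i in range(1, 6)]
        + [f"e{i}" for i in range(1, 5)] + [f"c{i}" for i in range(1, 5)]
    )
    return {
        "SUS": ScaleConfig(
            name="SUS",
            items=tuple(f"sus{i}" for i in range(1, 11)),
            aggregation="sus",
        ),
        "AQ-SF": ScaleConfig(
            name="AQ-SF",
            items=aq_items,
            subscales={
                "physical_aggression": aq_items[0:3],
                "verbal_aggression": aq_items[3:6],
                "anger": aq_items[6:9],
                "hostility": aq_items[9:12],
            },
        ),
        "STAXI-2": ScaleConfig(
            name="STAXI-2",
            items=staxi_items,
            response_max=4,
            subscales={
                "state_anger": staxi_items[0:5],
                "trait_anger": staxi_items[5:10],
                "anger_expression": staxi_items[10:14],
                "anger_control": staxi_items[14:18],
            },
        ),
        "ABSQ": ScaleConfig(
            name="ABSQ",
            items=tuple(f"absq{i}" for i in range(1, 19)),
        ),
    }


DEFAULT_SCALE_CONFIGS: dict[str, ScaleConfig] = _default_configs()


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a long-format item-response CSV
    (``respondent_id,timepoint,instrument,item_id,response``)."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "timepoint": str,
                                  "instrument": str, "item_id": str})
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns {sorted(missing)}")
    return df


def _score_items(values: pd.Series, config: ScaleConfig,
                 item_ids: Sequence[str]) -> float:
    """Prorated mean of the (reflected) responses to ``item_ids``."""
    answered = [i for i in item_ids if i in values.index and pd.notna(values[i])]
    if len(answered) < config.min_answered_fraction * len(item_ids):
        return float("nan")
    total = 0.0
    for i in answered:
        r = float(values[i])
        if not config.response_min <= r <= config.response_max:
            raise ValueError(
                f"{config.name} item {i} response {r} outside "
                f"[{config.response_min}, {config.response_max}]"
            )
        if i in config.reverse_items:
            r = config.response_max + config.response_min - r
        total += r
    return total / len(answered)


def scale_scores(table: pd.DataFrame, config: ScaleConfig) -> pd.DataFrame:
    """Score one instrument for every (respondent, timepoint) in ``table``.

    Returns a frame indexed by (respondent_id, timepoint) with a ``total``
    column and one column per subscale, all item means on the native
    response scale.  A score is NaN when fewer than 80% of its items were
    answered (SUS excepted: any missing item raises).
    """
    sub = table[table["instrument"] == config.name]
    records = []
    for (rid, tp), grp in sub.groupby(["respondent_id", "timepoint"], sort=True):
        values = grp.set_index("item_id")["response"]
        if values.index.duplicated().any():
            raise ValueError(f"duplicate item responses for {rid}/{tp}")
        if config.aggregation == "sus":
            row = {"total": sus_score([
                int(values[i]) if i in values.index else None
                for i in config.items
            ])}
        else:
            row = {"total": _score_items(values, config, config.items)}
            for name, ids in config.subscales.items():
                row[name] = _score_items(values, config, ids)
        records.append({"respondent_id": rid, "timepoint": tp, **row})
    if not records:
        empty = pd.MultiIndex.from_arrays(
            [[], []], names=["respondent_id", "timepoint"])
        return pd.DataFrame(columns=["total"], index=empty)
    return pd.DataFrame.from_records(records).set_index(
        ["respondent_id", "timepoint"])


# ---------------------------------------------------------------------------
# Statistics

@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # min(W+, W-)
    z: float  # signed like (W+ - W-)
    p: float  # two-sided
    n_effective: int
    method: str  # "exact" | "normal" | "degenerate"


def wilcoxon_matched_pairs(
    pre: Sequence[float],
    post: Sequence[float],
    zero_policy: str = "wilcox",
    exact_threshold: int = 15,
) -> WilcoxonResult:
    """Matched-pairs Wilcoxon signed-rank test on differences post − pre.

    Zero differences are dropped before ranking under the default
    ``"wilcox"`` policy; ``"pratt"`` ranks them with the rest and then
    discards their ranks.  |d| are ranked with average ties;
    W = min(W+, W−).  The two-sided p is exact — full enumeration of all
    sign assignments — when the effective n is at most ``exact_threshold``,
    else a tie-corrected, continuity-corrected normal approximation.
    The Z statistic carries the sign of (W+ − W−).
    """
    if zero_policy not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 1:
        raise ValueError("pre and post must be equal-length 1-d sequences")
    d = post - pre
    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff == 0:
        return WilcoxonResult(w=0.0, z=0.0, p=1.0, n_effective=0,
                              method="degenerate")

    if zero_policy == "wilcox":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]

    w_plus = float(ranks[d_used > 0].sum())
    w_minus = float(ranks[d_used < 0].sum())
    w = min(w_plus, w_minus)
    total = w_plus + w_minus

    # normal approximation; average ranks make sum(r^2)/4 the tie-corrected
    # variance, and the 0.5 is the continuity correction
    mu = total / 2.0
    sigma = float(np.sqrt(np.sum(ranks ** 2)) / 2.0)
    z_mag = max(mu - w - 0.5, 0.0) / sigma if sigma > 0 else 0.0
    z = z_mag if w_plus >= w_minus else -z_mag

    if n_eff <= exact_threshold:
        # enumerate all 2^n sign assignments of the ranked differences
        le = ge = count = 0
        for signs in itertools.product((0, 1), repeat=n_eff):
            wp = sum(r for s, r in zip(signs, ranks) if s)
            count += 1
            if wp <= w:
                le += 1
            if wp >= total - w:
                ge += 1
        p = min(1.0, (le + ge) / count)
        method = "exact"
    else:
        p = min(1.0, 2.0 * float(stats.norm.sf(z_mag)))
        method = "normal"
    return WilcoxonResult(w=w, z=z, p=p, n_effective=n_eff, method=method)


def pearson_r(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
) -> tuple[float, int, float]:
    """Correlation with df and two-sided p from the t transform.

    Returns (r, df, p) with df = n − 2.  ``method`` may be "spearman" for
    the rank correlation instead of the product-moment coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d sequences, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), len(x) - 2, float(res.pvalue)


def score_report(
    table: pd.DataFrame,
    configs: Mapping[str, ScaleConfig] | None = None,
    timepoints: tuple[str, str] = ("T0", "T1"),
) -> pd.DataFrame:
    """Pre/post summary per scale: mean, SD per timepoint and the
    matched-pairs Wilcoxon test over respondents present at both.

    Returns one row per (instrument, scale) with columns
    ``mean_<tp>``, ``sd_<tp>``, ``wilcoxon_w``, ``z``, ``p``, ``n_pairs``.
    """
    configs = dict(configs or DEFAULT_SCALE_CONFIGS)
    rows = []
    for name, config in configs.items():
        scored = scale_scores(table, config)
        if scored.empty:
            continue
        for col in scored.columns:
            wide = scored[col].unstack("timepoint")
            row: dict = {"instrument": name, "scale": col}
            for tp in timepoints:
                vals = wide[tp].dropna() if tp in wide else pd.Series(dtype=float)
                row[f"mean_{tp}"] = float(vals.mean()) if len(vals) else float("nan")
                row[f"sd_{tp}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            if all(tp in wide for tp in timepoints):
                paired = wide[list(timepoints)].dropna()
                if len(paired) >= 1:
                    res = wilcoxon_matched_pairs(
                        paired[timepoints[0]], paired[timepoints[1]])
                    row.update(wilcoxon_w=res.w, z=res.z, p=res.p,
                               n_pairs=len(paired))
            rows.append(row)
    return pd.DataFrame(rows)
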