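"""Barrage-level co-activity scores and activity-trend statistics.

Co-activity of a synapse with a comparison group (its ≤10 µm neighbors, its
domain partners, or synapses of other domains) is the fraction of the
barrages in which the synapse was active that also contained at least one
transmission event from the group, normalized by the group size:

    C = (# co-active barrages) / (# active barrages) / |group|,  C ∈ [0, 1].

Only events occurring inside barrages contribute.  The trend of a synapse's
activity across the recordings of an experiment is summarized by the
Mann–Kendall score S = Σ_{i<j} sign(f_j − f_i), positive for monotonic
frequency increases, negative for decreases, zero for flat series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .activity import Experiment, Synapse
from .domains import DomainSet
from .morphology import path_distance

__all__ = [
    "CoactivityScore",
    "coactivity",
    "local_coactivity",
    "domain_coactivity_contrast",
    "mann_kendall",
    "trend_scores",
    "trend_vs_coactivity",
]


@dataclass
class CoactivityScore:
    synapse_id: str
    group_label: str
    score: float
    n_active_barrages: int
    group_size: int


def _active_barrages(synapse: Synapse) -> set[str]:
    return {ev.barrage_id for ev in synapse.events if ev.barrage_id is not None}


def coactivity(
    focal: Synapse,
    group: list[Synapse],
    group_label: str = "group",
    method: str = "fraction",
) -> CoactivityScore | None:
    """Co-activity of ``focal`` with ``group``; None when undefined (empty
    group, or focal never active inside a barrage).

    method "fraction" (primary): fraction of the focal synapse's active
    barrages shared with ≥1 group member, divided by the group size.
    method "event_ratio" (alternative): focal event count divided by the
    group's event count within the focal synapse's active barrages, divided
    by the group size; unbounded above and undefined when the group is
    silent in those barrages.
    """
    group = [g for g in group if g.synapse_id != focal.synapse_id]
    active = _active_barrages(focal)
    if not group or not active:
        return None
    if method == "fraction":
        member_barrages = set()
        for g in group:
            member_barrages |= _active_barrages(g)
        co = len(active & member_barrages)
        score = co / len(active) / len(group)
    elif method == "event_ratio":
        focal_events = sum(1 for ev in focal.events if ev.barrage_id in active)
        group_events = sum(
            1 for g in group for ev in g.events if ev.barrage_id in active
        )
        if group_events == 0:
            return None
        score = focal_events / group_events / len(group)
    else:
        raise ValueError(f"unknown co-activity method {method!r}")
    return CoactivityScore(
        synapse_id=focal.synapse_id,
        group_label=group_label,
        score=float(score),
        n_active_barrages=len(active),
        group_size=len(group),
    )


def local_coactivity(
    experiment: Experiment, radius_um: float = 10.0, method: str = "fraction"
) -> pd.DataFrame:
    """Each synapse's co-activity with its neighbors within ``radius_um``
    proximally and distally along the dendrite."""
    rows = []
    for s in experiment.synapses:
        group = [
            o
            for o in experiment.synapses
            if o.synapse_id != s.synapse_id
            and path_distance(experiment.tree, s.position, o.position) <= radius_um
        ]
        sc = coactivity(s, group, "neighbors-10um", method)
        if sc is not None:
            rows.append(
                {
                    "synapse_id": s.synapse_id,
                    "coactivity": sc.score,
                    "n_active_barrages": sc.n_active_barrages,
                    "group_size": sc.group_size,
                }
            )
    return pd.DataFrame(rows, columns=[
        "synapse_id", "coactivity", "n_active_barrages", "group_size"])


def domain_coactivity_contrast(
    experiment: Experiment,
    domain_set: DomainSet,
    radius_um: float = 10.0,
    method: str = "fraction",
) -> dict:
    """Domain-resolved co-activity comparisons.

    Returns a dict with

    * ``paired``: per in-domain synapse, co-activity with its same-domain
      partners vs with synapses of other domains (synapses whose either
      group is empty or that were never active in a barrage are excluded),
      with a Wilcoxon signed-rank test;
    * ``in_out``: local (≤ radius) co-activity of in-domain vs outside
      synapses, with a Mann–Whitney U test;
    * per-experiment means of the paired values.
    """
    membership = domain_set.membership()
    by_id = {s.synapse_id: s for s in experiment.synapses}
    paired_rows = []
    for dom in domain_set.domains:
        ids = dom.all_ids
        others = [
            by_id[i]
            for d2 in domain_set.domains
            if d2.domain_id != dom.domain_id
            for i in d2.all_ids
        ]
        for sid in ids:
            s = by_id[sid]
            same = [by_id[i] for i in ids if i != sid]
            sc_within = coactivity(s, same, "same-domain", method)
            sc_other = coactivity(s, others, "other-domains", method) if others else None
            if sc_within is not None and sc_other is not None:
                paired_rows.append(
                    {
                        "synapse_id": sid,
                        "domain_id": dom.domain_id,
                        "within": sc_within.score,
                        "other": sc_other.score,
                    }
                )
    paired = pd.DataFrame(paired_rows, columns=[
        "synapse_id", "domain_id", "within", "other"])

    local = local_coactivity(experiment, radius_um, method)
    in_ids = domain_set.in_domain_ids()
    local["in_domain"] = local["synapse_id"].isin(in_ids)

    out: dict = {"paired": paired, "in_out": local}
    if len(paired) >= 2 and not np.allclose(paired["within"], paired["other"]):
        w = stats.wilcoxon(paired["within"], paired["other"])
        out["paired_statistic"] = float(w.statistic)
        out["paired_p"] = float(w.pvalue)
    vals_in = local.loc[local["in_domain"], "coactivity"]
    vals_out = local.loc[~local["in_domain"], "coactivity"]
    out["mean_within"] = float(paired["within"].mean()) if len(paired) else np.nan
    out["mean_other"] = float(paired["other"].mean()) if len(paired) else np.nan
    out["mean_in"] = float(vals_in.mean()) if len(vals_in) else np.nan
    out["mean_out"] = float(vals_out.mean()) if len(vals_out) else np.nan
    if len(vals_in) >= 1 and len(vals_out) >= 1:
        u = stats.mannwhitneyu(vals_in, vals_out, alternative="two-sided")
        out["in_out_statistic"] = float(u.statistic)
        out["in_out_p"] = float(u.pvalue)
    return out


def mann_kendall(series) -> int:
    """Mann–Kendall score S = Σ_{i<j} sign(x_j − x_i); ties contribute 0."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("Mann–Kendall score needs at least 2 recordings")
    diff = x[None, :] - x[:, None]
    return int(np.sign(diff[np.triu_indices(len(x), k=1)]).sum())


def trend_scores(experiment: Experiment) -> pd.DataFrame:
    """Per-synapse Mann–Kendall score over the experiment's recording
    sequence of per-recording frequencies."""
    order = [r.recording_id for r in experiment.recordings]
    rows = []
    for s in experiment.synapses:
        if not s.f_per_recording:
            raise ValueError("per-recording frequencies not computed")
        series = [s.f_per_recording[r] for r in order]
        rows.append(
            {"synapse_id": s.synapse_id, "mk_score": mann_kendall(series)}
        )
    return pd.DataFrame(rows)


def trend_vs_coactivity(
    synapses: list[Synapse],
    coactivity_df: pd.DataFrame,
    trend_df: pd.DataFrame,
    f_min: float = 0.6,
) -> dict:
    """OLS regression of the Mann–Kendall score on local co-activity over
    synapses with overall frequency ≥ f_min (default 0.6 min⁻¹)."""
    f_by_id = {s.synapse_id: s.f for s in synapses}
    df = coactivity_df.merge(trend_df, on="synapse_id")
    df["f"] = df["synapse_id"].map(f_by_id)
    df = df[df["f"] >= f_min].reset_index(drop=True)
    if len(df) < 3:
        raise ValueError(
            f"only {len(df)} synapses pass the f ≥ {f_min} min⁻¹ filter; "
            "need at least 3 for a regression"
        )
    x = df["coactivity"].to_numpy(dtype=float)
    y = df["mk_score"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("co-activity constant across synapses: degenerate design",
                      stacklevel=2)
        return {"slope": np.nan, "intercept": float(y.mean()), "p_value": np.nan,
                "r_squared": np.nan, "n": int(len(df)), "data": df}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "p_value": float(model.pvalues[1]),
        "r_squared": float(model.rsquared),
        "n": int(len(df)),
        "data": df,
    }
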