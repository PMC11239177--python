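"""End-to-end pipeline: detection → filtering → classification → spatial
test → domains → co-activity → trends → statistical report.

Two entry points exist: from raw signals (ΔF traces + somatic current, via
:func:`detect_experiment`) or from pre-extracted event tables (an
:class:`~dendrodomains.activity.Experiment` built directly, e.g. by the
synthetic generator), after which every downstream stage is identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .activity import (
    Experiment,
    Recording,
    Synapse,
    classify_high_activity,
    compute_frequencies,
    filter_active,
    synapse_summary_table,
)
from .coactivity import (
    domain_coactivity_contrast,
    local_coactivity,
    trend_scores,
    trend_vs_coactivity,
)
from .detection import (
    BarrageConfig,
    CurrentTrace,
    RoiTrace,
    associate_events,
    detect_barrages,
    detect_events,
    estimate_noise,
    geometric_bins,
    zscore_amplitudes,
)
from .domains import assign_domains, domain_metrics
from .io import (
    barrages_to_frame,
    config_hash,
    events_to_frame,
    write_json,
    write_table,
)
from .morphology import DendriteTree, TreePosition
from .spatial import ShuffleConfig, distance_to_high_activity, shuffle_test

log = logging.getLogger("dendrodomains")

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "detect_experiment",
    "run_pipeline",
    "compare_groups",
]


@dataclass
class PipelineConfig:
    """All stage parameters; the defaults are the study's rule set."""

    # event detection
    event_threshold_sigma: float = 2.0
    min_event_frames: int = 2
    association_tolerance_s: float = 0.2
    barrage: BarrageConfig = field(default_factory=BarrageConfig)
    # activity filters
    f_min: float = 0.03  # min⁻¹, functional-synapse inclusion
    high_activity_percentile: float = 80.0
    per_dendrite_percentile: bool = False
    # spatial shuffle test
    empty_spacing_um: float = 4.0
    n_shuffles: int = 100
    shuffle_mode: str = "pooled"
    # domain rules
    r_merge_um: float = 10.0
    r_member_um: float = 10.0
    r_tiebreak_um: float = 20.0
    pad_um: float = 5.0
    # co-activity and trends
    coactivity_radius_um: float = 10.0
    coactivity_method: str = "fraction"
    f_min_regression: float = 0.6  # min⁻¹
    seed: int = 0
    version: str = "1"


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    stats: dict
    config_hash: str


def detect_experiment(
    tree: DendriteTree,
    positions: pd.DataFrame,
    roi_traces: list[RoiTrace],
    current_traces: dict[str, CurrentTrace],
    age: int,
    config: PipelineConfig | None = None,
    dendrite_id: str = "d0",
) -> Experiment:
    """Raw-signal entry point: detect events and barrages, associate them,
    z-score amplitudes, and assemble an Experiment.

    ``positions`` needs columns synapse_id, edge_id, offset_um, type; ROI ids
    of the ΔF traces must match the synapse ids.
    """
    cfg = config or PipelineConfig()
    rec_ids = sorted({tr.recording_id for tr in roi_traces})
    durations = {}
    for tr in roi_traces:
        durations[tr.recording_id] = (tr.times[-1] - tr.times[0] + np.median(
            np.diff(tr.times))) / 60.0
    recordings = [Recording(r, float(durations[r])) for r in rec_ids]

    events = []
    for tr in roi_traces:
        sigma = estimate_noise(tr)
        if sigma <= 0:
            log.warning("ROI %s/%s: flat trace, skipped", tr.roi_id,
                        tr.recording_id)
            continue
        evs = detect_events(
            tr, sigma,
            threshold_sigma=cfg.event_threshold_sigma,
            min_frames=cfg.min_event_frames,
        )
        events.extend(evs)
    barrages = []
    for rec, ctr in current_traces.items():
        barrages.extend(detect_barrages(ctr, cfg.barrage))
    events = associate_events(events, barrages, cfg.association_tolerance_s)
    events = zscore_amplitudes(events)
    log.info("detected %d events, %d barrages", len(events), len(barrages))

    synapses = []
    for row in positions.itertuples(index=False):
        sid = str(row.synapse_id)
        synapses.append(
            Synapse(
                synapse_id=sid,
                position=TreePosition(int(row.edge_id), float(row.offset_um)),
                kind=str(row.type),
                events=[e for e in events if e.synapse_id == sid],
            )
        )
    return Experiment(
        dendrite_id=dendrite_id,
        tree=tree,
        synapses=synapses,
        recordings=recordings,
        barrages=barrages,
        age=age,
    )


def compare_groups(
    a, b, paired: bool = False, test: str = "auto"
) -> dict:
    """Two-sided group comparison with means ± SEM.

    test: "ttest" (Student), "mannwhitney" (unpaired ranks), "wilcoxon"
    (paired ranks) or "auto" (t-test of the requested pairing).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "auto":
        test = "ttest"
    if paired and len(a) != len(b):
        raise ValueError(f"{test}: paired samples must have equal length")
    min_n = 2
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"{test}: need at least {min_n} values per group")
    if test == "ttest":
        r = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
    elif test == "mannwhitney":
        if paired:
            raise ValueError("mannwhitney is an unpaired test")
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "wilcoxon":
        if not paired:
            raise ValueError("wilcoxon is a paired test")
        if np.allclose(a, b):
            return {
                "test": test, "statistic": np.nan, "p_value": 1.0,
                "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "sem_a": float(stats.sem(a)), "sem_b": float(stats.sem(b)),
                "n_a": int(len(a)), "n_b": int(len(b)),
            }
        r = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "test": test,
        "statistic": float(r.statistic),
        "p_value": float(r.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sem_a": float(stats.sem(a)),
        "sem_b": float(stats.sem(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
    }


def _age_regression(df: pd.DataFrame, ycol: str) -> dict:
    """OLS of a per-experiment quantity on postnatal day, with 95% CI."""
    d = df.dropna(subset=[ycol])
    if len(d) < 3 or d["age"].nunique() < 2:
        return {"slope": np.nan, "p_value": np.nan, "n": int(len(d))}
    x = sm.add_constant(d["age"].to_numpy(dtype=float))
    m = sm.OLS(d[ycol].to_numpy(dtype=float), x).fit()
    lo, hi = m.conf_int()[1]
    return {
        "slope": float(m.params[1]),
        "intercept": float(m.params[0]),
        "p_value": float(m.pvalues[1]),
        "ci95": [float(lo), float(hi)],
        "n": int(len(d)),
    }


def run_pipeline(
    experiments: list[Experiment],
    config: PipelineConfig | None = None,
    out_dir=None,
) -> ReportBundle:
    """Run every analysis stage over a cohort of experiments and assemble
    the statistical report.  Deterministic given the config seed."""
    cfg = config or PipelineConfig()
    chash = config_hash(cfg)
    tables: dict[str, pd.DataFrame] = {}
    stats_out: dict = {"config_hash": chash}

    # --- frequencies and functional filter ---------------------------------
    for e in experiments:
        compute_frequencies(e)
        n0 = len(e.synapses)
        e.synapses = filter_active(e.synapses, cfg.f_min)
        log.info("%s: %d/%d synapses pass f >= %g min^-1",
                 e.dendrite_id, len(e.synapses), n0, cfg.f_min)

    thresholds = classify_high_activity(
        experiments,
        percentile=cfg.high_activity_percentile,
        per_dendrite=cfg.per_dendrite_percentile,
    )
    stats_out["high_activity_thresholds"] = thresholds

    # --- per-experiment stages ---------------------------------------------
    event_rows, barrage_rows = [], []
    shuffle_rows, domain_rows, dendrite_rows = [], [], []
    coact_frames, paired_frames, trend_frames, dist_frames = [], [], [], []
    per_exp_rows = []
    for k, e in enumerate(experiments):
        pooled = [ev for s in e.synapses for ev in s.events]
        if e.barrages and not any(ev.barrage_id for ev in pooled):
            # raw event tables arrive unassociated; generator output (and
            # re-runs) carry their associations already
            pooled = associate_events(pooled, e.barrages,
                                      cfg.association_tolerance_s)
        else:
            counts: dict[str, int] = {}
            for ev in pooled:
                if ev.barrage_id is not None:
                    counts[ev.barrage_id] = counts.get(ev.barrage_id, 0) + 1
            for b in e.barrages:
                b.n_events = counts.get(b.barrage_id, 0)
        all_events = zscore_amplitudes(pooled)
        by_syn: dict[str, list] = {}
        for ev in all_events:
            by_syn.setdefault(ev.synapse_id, []).append(ev)
        for s in e.synapses:
            s.events = by_syn.get(s.synapse_id, [])
        ef = events_to_frame(all_events)
        ef.insert(0, "dendrite_id", e.dendrite_id)
        event_rows.append(ef)
        bf = barrages_to_frame(e.barrages)
        bf.insert(0, "dendrite_id", e.dendrite_id)
        barrage_rows.append(bf)

        if len(e.synapses) >= 2:
            sh = shuffle_test(
                e.tree,
                e.synapses,
                ShuffleConfig(
                    n_shuffles=cfg.n_shuffles,
                    spacing_um=cfg.empty_spacing_um,
                    seed=cfg.seed * 100003 + k,
                    mode=cfg.shuffle_mode,
                ),
            )
            shuffle_rows.append(
                {
                    "dendrite_id": e.dendrite_id,
                    "age": e.age,
                    "age_group": e.age_group,
                    "ks_D": sh.statistic,
                    "p_value": sh.p_value,
                    "n_synapses": len(e.synapses),
                    "n_candidates": sh.n_candidates,
                }
            )

        dset = assign_domains(
            e.tree, e.synapses,
            r_merge=cfg.r_merge_um, r_member=cfg.r_member_um,
            r_tiebreak=cfg.r_tiebreak_um, pad=cfg.pad_um,
        )
        ddf, dsum = domain_metrics(dset, e.tree, e.dendrite_id)
        if len(ddf):
            ddf["age"] = e.age
            ddf["age_group"] = e.age_group
            domain_rows.append(ddf)
        dsum.update({"age": e.age, "age_group": e.age_group})

        contrast = domain_coactivity_contrast(
            e, dset, cfg.coactivity_radius_um, cfg.coactivity_method)
        local = contrast["in_out"].copy()
        local["dendrite_id"] = e.dendrite_id
        local["age_group"] = e.age_group
        coact_frames.append(local)
        pr = contrast["paired"].copy()
        if len(pr):
            pr["dendrite_id"] = e.dendrite_id
            paired_frames.append(pr)

        tdf = trend_scores(e)
        tdf["dendrite_id"] = e.dendrite_id
        in_ids = dset.in_domain_ids()
        tdf["in_domain"] = tdf["synapse_id"].isin(in_ids)
        trend_frames.append(tdf)

        hdf, hsum = distance_to_high_activity(e.tree, e.synapses)
        if len(hdf):
            hdf["dendrite_id"] = e.dendrite_id
            dist_frames.append(hdf)

        n_assoc = sum(ev.barrage_id is not None for ev in all_events)
        per_exp_rows.append(
            {
                "dendrite_id": e.dendrite_id,
                "age": e.age,
                "age_group": e.age_group,
                "n_synapses": len(e.synapses),
                "dendrite_length_um": e.tree.total_length,
                "synapse_density_per_100um":
                    100.0 * len(e.synapses) / e.tree.total_length,
                "mean_f": float(np.mean([s.f for s in e.synapses]))
                    if e.synapses else np.nan,
                "input_rate_per_100um":
                    100.0 * sum(len(s.events) for s in e.synapses)
                    / e.total_minutes / e.tree.total_length,
                "pct_spine": 100.0 * np.mean(
                    [s.kind == "spine" for s in e.synapses])
                    if e.synapses else np.nan,
                "n_events": len(all_events),
                "frac_events_in_barrages":
                    n_assoc / len(all_events) if all_events else np.nan,
                "barrage_rate_per_min":
                    len(e.barrages) / e.total_minutes,
                "mean_barrage_charge_pC": float(np.mean(
                    [b.charge_pC for b in e.barrages])) if e.barrages else np.nan,
                "mean_events_per_barrage": float(np.mean(
                    [b.n_events for b in e.barrages])) if e.barrages else np.nan,
                "within_coactivity": contrast["mean_within"],
                "other_coactivity": contrast["mean_other"],
                **{k2: dsum[k2] for k2 in (
                    "n_domains", "domain_density_per_100um", "coverage",
                    "pct_synapses_in_domains")},
            }
        )

    tables["synapses"] = synapse_summary_table(experiments)
    tables["events"] = pd.concat(event_rows, ignore_index=True) if event_rows \
        else pd.DataFrame()
    tables["barrages"] = pd.concat(barrage_rows, ignore_index=True) \
        if barrage_rows else pd.DataFrame()
    tables["experiments"] = pd.DataFrame(per_exp_rows)
    tables["shuffle_tests"] = pd.DataFrame(shuffle_rows)
    tables["domains"] = pd.concat(domain_rows, ignore_index=True) \
        if domain_rows else pd.DataFrame()
    tables["local_coactivity"] = pd.concat(coact_frames, ignore_index=True) \
        if coact_frames else pd.DataFrame()
    tables["paired_coactivity"] = pd.concat(paired_frames, ignore_index=True) \
        if paired_frames else pd.DataFrame()
    tables["trends"] = pd.concat(trend_frames, ignore_index=True)
    tables["distance_to_high_activity"] = (
        pd.concat(dist_frames, ignore_index=True) if dist_frames
        else pd.DataFrame())

    stats_out.update(_report_stats(tables, experiments, cfg))

    if out_dir is not None:
        for name, df in tables.items():
            write_table(df, f"{out_dir}/{name}.tsv", chash)
        write_json(stats_out, f"{out_dir}/report.json")
    return ReportBundle(tables=tables, stats=stats_out, config_hash=chash)


def _report_stats(
    tables: dict[str, pd.DataFrame],
    experiments: list[Experiment],
    cfg: PipelineConfig,
) -> dict:
    out: dict = {}
    exp = tables["experiments"]

    # developmental regressions (per-experiment means on postnatal day)
    for ycol in ("synapse_density_per_100um", "mean_f", "input_rate_per_100um",
                 "pct_spine", "barrage_rate_per_min", "mean_barrage_charge_pC",
                 "mean_events_per_barrage"):
        out[f"age_regression/{ycol}"] = _age_regression(exp, ycol)

    # spine vs shaft transmission frequency per age group
    syn = tables["synapses"]
    for grp, d in syn.groupby("age_group"):
        spine = d.loc[d["type"] == "spine", "f"].to_numpy(dtype=float)
        shaft = d.loc[d["type"] == "shaft", "f"].to_numpy(dtype=float)
        if len(spine) >= 2 and len(shaft) >= 2:
            out[f"spine_vs_shaft/{grp}"] = compare_groups(
                spine, shaft, test="mannwhitney")

    # events-per-barrage vs charge, and amplitude vs geometrically binned
    # barrage size (pooled over experiments)
    ev = tables["events"]
    ba = tables["barrages"]
    if len(ev) and len(ba):
        merged = ev.dropna(subset=["barrage_id"]).merge(
            ba[["dendrite_id", "barrage_id", "charge_pC", "n_events"]],
            on=["dendrite_id", "barrage_id"],
        )
        if len(merged) >= 3 and merged["charge_pC"].gt(0).all():
            r = stats.pearsonr(ba["charge_pC"], ba["n_events"])
            out["charge_vs_events_per_barrage"] = {
                "r": float(r.statistic), "p_value": float(r.pvalue),
                "n": int(len(ba)),
            }
            edges, _ = geometric_bins(merged["charge_pC"].to_numpy())
            merged["charge_bin"] = np.digitize(merged["charge_pC"], edges) - 1
            zb = merged.dropna(subset=["z_amplitude"]).groupby("charge_bin")[
                "z_amplitude"].mean()
            if len(zb) >= 3:
                sr = stats.spearmanr(zb.index.to_numpy(), zb.to_numpy())
                out["z_amplitude_vs_charge_bin"] = {
                    "spearman_r": float(sr.statistic),
                    "p_value": float(sr.pvalue),
                    "n_bins": int(len(zb)),
                }

    # near vs far from high-activity synapses (pooled)
    dd = tables["distance_to_high_activity"]
    if len(dd):
        near = dd.loc[dd["group"] == "near", "f"].to_numpy(dtype=float)
        far = dd.loc[dd["group"] == "far", "f"].to_numpy(dtype=float)
        if len(near) >= 2 and len(far) >= 2:
            out["near_vs_far_high_activity"] = compare_groups(near, far)

    # domain metrics young vs old
    dom = tables["domains"]
    if len(dom) and dom["age_group"].nunique() == 2:
        young = dom[dom["age_group"] == "P8-10"]
        old = dom[dom["age_group"] == "P12-13"]
        for col in ("extent_um", "n_synapses"):
            if len(young) >= 2 and len(old) >= 2:
                out[f"domain_{col}_young_vs_old"] = compare_groups(
                    young[col], old[col])
    if exp["age_group"].nunique() == 2:
        young = exp[exp["age_group"] == "P8-10"]
        old = exp[exp["age_group"] == "P12-13"]
        for col in ("domain_density_per_100um", "coverage"):
            out[f"{col}_young_vs_old"] = compare_groups(young[col], old[col])

    # co-activity contrasts
    lc = tables["local_coactivity"]
    if len(lc):
        cin = lc.loc[lc["in_domain"], "coactivity"].to_numpy(dtype=float)
        cout = lc.loc[~lc["in_domain"], "coactivity"].to_numpy(dtype=float)
        if len(cin) >= 2 and len(cout) >= 2:
            out["coactivity_in_vs_out_domain"] = compare_groups(
                cin, cout, test="mannwhitney")
    pc = tables["paired_coactivity"]
    if len(pc) >= 2:
        out["coactivity_within_vs_other_synapse"] = compare_groups(
            pc["within"], pc["other"], paired=True, test="wilcoxon")
        per_exp = pc.groupby("dendrite_id")[["within", "other"]].mean()
        if len(per_exp) >= 2:
            out["coactivity_within_vs_other_experiment"] = compare_groups(
                per_exp["within"], per_exp["other"], paired=True,
                test="wilcoxon")

    # trends: in- vs out-domain MK scores, and MK vs local co-activity
    tr = tables["trends"]
    s_in = tr.loc[tr["in_domain"], "mk_score"].to_numpy(dtype=float)
    s_out = tr.loc[~tr["in_domain"], "mk_score"].to_numpy(dtype=float)
    if len(s_in) >= 2 and len(s_out) >= 2:
        out["mk_in_vs_out_domain"] = compare_groups(s_in, s_out)
    all_syn = [s for e in experiments for s in e.synapses]
    if "synapse_id" not in lc.columns:
        out["mk_vs_coactivity"] = {"error": "no co-activity scores"}
        return out
    try:
        reg = trend_vs_coactivity(
            all_syn,
            lc[["synapse_id", "coactivity"]],
            tr[["synapse_id", "mk_score"]],
            f_min=cfg.f_min_regression,
        )
        out["mk_vs_coactivity"] = {
            k: reg[k] for k in ("slope", "intercept", "p_value",
                                "r_squared", "n")
        }
    except ValueError as err:
        out["mk_vs_coactivity"] = {"error": str(err)}
    return out
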