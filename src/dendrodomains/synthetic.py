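"""Ground-truth generator for synthetic dendritic-imaging experiments.

Emulates the statistical structure the analysis assumes, with every latent
variable exposed as ground truth:

* synapse placement clustered into dendritic domains (plus a uniform
  background), each domain anchored by a high-release synapse near its
  center;
* long-tailed per-synapse release propensities (lognormal, with a released
  multiplier for the high-release minority), so most synapses transmit
  rarely and a few transmit often;
* barrage-structured input: a renewal process of compound-input episodes
  (≥ 3 s apart) recruits whole domains, within which synapses fire
  Bernoulli-per-barrage; a low background rate adds out-of-barrage events;
* event amplitudes increasing with barrage size (multi-vesicular release);
* optional monotonic frequency ramps across recordings, by default coupled
  to domain membership (inside: up, outside: down);
* optional rendering to raw signals: ΔF traces (calcium-indicator kernel +
  Gaussian noise) and the 10 kHz somatic current (one EPSC per event,
  including the unimaged majority of inputs, + noise).

The "young" and "old" presets mirror the beginning and end of the second
postnatal week: sparser domains, smaller domains and lower transmission
frequencies in the young configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .activity import Experiment, Recording, Synapse, compute_frequencies
from .detection import Barrage, CurrentTrace, RoiTrace, TransmissionEvent
from .morphology import DendriteTree, TreePosition

__all__ = ["GeneratorConfig", "GroundTruth", "preset", "generate_experiment",
           "generate_cohort", "render_traces"]


@dataclass
class GeneratorConfig:
    seed: int = 0
    # morphology
    dendrite_length_um: float = 150.0
    n_branch_points: int = 0
    # placement
    domain_density_per_100um: float = 2.0
    domain_extent_mean_um: float = 21.0
    domain_extent_sd_um: float = 4.0
    synapses_per_domain_mean: float = 4.5
    background_density_per_100um: float = 2.0
    spine_prob_high: float = 0.76
    spine_prob_normal: float = 0.40
    # release statistics
    freq_scale: float = 1.0  # global multiplier on recruitment/background rates
    freq_lognorm_sigma: float = 0.4
    high_release_fraction: float = 0.2  # designed share of anchors
    high_release_multiplier: float = 4.5
    high_release_sigma: float = 0.3
    # barrage process
    barrage_rate_per_min: float = 3.0
    min_barrage_gap_s: float = 3.0
    barrage_duration_range_s: tuple[float, float] = (1.2, 3.0)
    barrage_size_sigma: float = 0.4
    barrage_size_min: float = 0.6
    # event model: barrage size scales recruitment and background firing,
    # so larger barrages carry more events and larger charges
    p_domain_recruit: float = 0.35
    p_fire_given_recruit: float = 0.2
    p_background_fire: float = 0.02
    member_radius_um: float = 10.0  # members placed within this of an anchor
    lone_high_fraction: float = 0.4  # share of spare anchors placed alone
    out_of_barrage_rate_per_min: float = 0.1
    lone_out_rate_per_min: float = 0.25  # lone anchors fire out of sync
    amplitude_scale: float = 1.0
    amplitude_charge_beta: float = 0.5
    amplitude_noise_sigma: float = 0.25
    # trends across recordings
    trend_fraction: float = 0.6
    trend_magnitude: float = 0.8
    trend_mode: str = "coupled"  # coupled | positive | negative | random | none
    # acquisition
    n_recordings: int = 10
    recording_duration_min: float = 3.0
    frame_rate_hz: float = 10.0
    trace_noise_sd: float = 0.15
    gcamp_rise_s: float = 0.1
    gcamp_decay_s: float = 0.6
    epsc_amp_pA: float = 8.0
    epsc_decay_ms: float = 20.0
    current_noise_pA: float = 1.0
    hidden_input_rate_per_s: float = 40.0  # unimaged inputs during a barrage
    age: int = 12


@dataclass
class GroundTruth:
    domain_membership: dict[str, int | None]  # synapse -> domain index
    high_release: dict[str, bool]
    trend_sign: dict[str, int]
    events: list[TransmissionEvent]  # with true barrage assignment
    barrages: list[Barrage]  # true windows
    barrage_size: dict[str, float]  # latent relative size per barrage
    propensity: dict[str, float] = field(default_factory=dict)


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """Named study conditions: "young" ≈ P8–10, "old" ≈ P12–13."""
    if name == "young":
        return GeneratorConfig(
            seed=seed,
            age=9,
            domain_density_per_100um=1.2,
            domain_extent_mean_um=19.0,
            synapses_per_domain_mean=4.0,
            background_density_per_100um=2.0,
            freq_scale=0.4,
        )
    if name == "old":
        return GeneratorConfig(
            seed=seed,
            age=12,
            domain_density_per_100um=2.5,
            domain_extent_mean_um=23.0,
            synapses_per_domain_mean=5.5,
            background_density_per_100um=2.0,
            freq_scale=1.0,
        )
    raise ValueError(f"unknown preset {name!r}; use 'young' or 'old'")


def _make_tree(cfg: GeneratorConfig) -> DendriteTree:
    if cfg.n_branch_points == 0:
        return DendriteTree.line(cfg.dendrite_length_um)
    # caterpillar: trunk carries 60% of the length, side branches the rest
    nb = cfg.n_branch_points
    trunk = 0.6 * cfg.dendrite_length_um
    side = 0.4 * cfg.dendrite_length_um / nb
    seg = trunk / (nb + 1)
    nodes = {1: (0.0, 0.0, 0.0)}
    edges = []
    nid = 1
    prev = 1
    for k in range(nb):
        nid += 1
        nodes[nid] = (seg * (k + 1), 0.0, 0.0)
        edges.append((prev, nid))
        branch_node = nid
        nid += 1
        nodes[nid] = (seg * (k + 1), side, 0.0)
        edges.append((branch_node, nid))
        prev = branch_node
    nid += 1
    nodes[nid] = (trunk, 0.0, 0.0)
    edges.append((prev, nid))
    return DendriteTree(nodes, edges, root=1)


def _uniform_position(tree: DendriteTree, rng: np.random.Generator) -> TreePosition:
    edges = tree.edges
    lengths = np.array([tree.edge_length[e] for e in edges])
    e = edges[rng.choice(len(edges), p=lengths / lengths.sum())]
    return TreePosition(e, float(rng.uniform(0, tree.edge_length[e])))


def _walk(
    tree: DendriteTree, pos: TreePosition, delta: float, rng: np.random.Generator
) -> TreePosition:
    """Move |delta| µm from pos along the tree (negative: toward the root),
    choosing uniformly at branch points and clipping at root/tips."""
    edge, off = pos.edge, pos.offset
    remaining = abs(float(delta))
    going_up = delta < 0
    while remaining > 1e-12:
        if going_up:
            step = min(remaining, off)
            off -= step
            remaining -= step
            if remaining <= 1e-12:
                break
            node = tree.parent[edge]
            if node == tree.root:
                break
            edge, off = node, tree.edge_length[node]
        else:
            length = tree.edge_length[edge]
            step = min(remaining, length - off)
            off += step
            remaining -= step
            if remaining <= 1e-12:
                break
            children = tree.children[edge]
            if not children:
                break
            edge, off = children[int(rng.integers(len(children)))], 0.0
    return TreePosition(edge, off)


def generate_experiment(
    config: GeneratorConfig, dendrite_id: str = "sim0"
) -> tuple[Experiment, GroundTruth]:
    """Draw one synthetic experiment (observables) plus its ground truth.
    Identical config (including seed) gives identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = _make_tree(cfg)
    L = tree.total_length

    # --- synapse placement -------------------------------------------------
    lam = cfg.domain_density_per_100um * L / 100.0
    # density 0 is the unstructured control: purely background placement
    n_domains = 0 if lam == 0 else max(1, int(rng.poisson(lam)))
    max_extent = min(cfg.domain_extent_mean_um + 3 * cfg.domain_extent_sd_um, L)
    if cfg.domain_extent_mean_um > L:
        raise ValueError("domain extent exceeds dendrite length")
    positions: list[TreePosition] = []
    membership: list[int | None] = []
    is_high: list[bool] = []
    # draw domain specs first, then allocate anchors so that the designed
    # high-release synapses make up the target fraction of all synapses
    specs = []
    for d in range(n_domains):
        specs.append(
            {
                "center": _uniform_position(tree, rng),
                "extent": float(
                    np.clip(
                        rng.normal(
                            cfg.domain_extent_mean_um, cfg.domain_extent_sd_um
                        ),
                        10.0,
                        max_extent,
                    )
                ),
                "n_syn": max(2, int(rng.poisson(cfg.synapses_per_domain_mean))),
                "n_high": 1,
            }
        )
    n_bg = int(rng.poisson(cfg.background_density_per_100um * L / 100.0))
    n_total = sum(sp["n_syn"] for sp in specs) + n_bg
    target = max(
        n_domains, int(round(cfg.high_release_fraction * n_total))
    )
    # part of the high-release budget goes to lone synapses without domain
    # partners: very active but out of sync with their neighborhood, each
    # forming a singleton domain
    n_lone = min(int(round(cfg.lone_high_fraction * target)),
                 max(0, target - n_domains))
    # remaining extra anchors go to the largest domains (high-activity
    # synapses cluster near each other), at most one extra per domain
    extras = target - n_domains - n_lone
    for sp in sorted(specs, key=lambda s: -s["n_syn"]):
        if extras <= 0 or sp["n_syn"] < 4:
            break
        sp["n_high"] = 2
        extras -= 1

    for d, sp in enumerate(specs):
        center, extent, n_syn, n_high = (
            sp["center"], sp["extent"], sp["n_syn"], sp["n_high"])
        spread = float(np.clip((extent - 18.0) / 2.0, 1.0, 4.0))
        anchor_deltas = [0.0] if n_high == 1 else [-spread, spread]
        anchor_pos = [_walk(tree, center, dlt, rng) for dlt in anchor_deltas]
        for k in range(n_syn):
            if k < n_high:
                positions.append(anchor_pos[k])
            else:
                # members stay within the 10 µm neighborhood of an anchor,
                # keeping generative membership consistent with the rules
                base = anchor_pos[int(rng.integers(n_high))]
                r = min(cfg.member_radius_um, extent / 2.0)
                positions.append(
                    _walk(tree, base, float(rng.uniform(-r, r)), rng)
                )
            membership.append(d)
            is_high.append(k < n_high)
    for j in range(n_lone):
        positions.append(_uniform_position(tree, rng))
        membership.append(n_domains + j)
        is_high.append(True)
    for _ in range(n_bg - n_lone):
        positions.append(_uniform_position(tree, rng))
        membership.append(None)
        is_high.append(False)
    n_domains_total = n_domains + n_lone
    domain_size = {d: membership.count(d) for d in range(n_domains_total)}

    n = len(positions)
    ids = [f"{dendrite_id}_s{i}" for i in range(n)]
    kinds = [
        "spine"
        if rng.random() < (cfg.spine_prob_high if hi else cfg.spine_prob_normal)
        else "shaft"
        for hi in is_high
    ]

    # --- release propensities ---------------------------------------------
    q = np.where(
        is_high,
        cfg.high_release_multiplier
        * rng.lognormal(0.0, cfg.high_release_sigma, size=n),
        rng.lognormal(0.0, cfg.freq_lognorm_sigma, size=n),
    )

    # --- trend signs -------------------------------------------------------
    signs = np.zeros(n, dtype=int)
    for i in range(n):
        lone_high = (
            is_high[i]
            and membership[i] is not None
            and domain_size[membership[i]] == 1
        )
        if cfg.trend_mode == "coupled" and lone_high:
            # a high-release synapse without in-sync partners always
            # depresses, whatever the trend fraction
            signs[i] = -1
            continue
        if cfg.trend_mode == "none" or rng.random() >= cfg.trend_fraction:
            continue
        if cfg.trend_mode == "coupled":
            # synapses with in-sync domain partners potentiate; lone and
            # out-of-domain synapses depress
            has_partners = (
                membership[i] is not None and domain_size[membership[i]] >= 2
            )
            signs[i] = 1 if has_partners else -1
        elif cfg.trend_mode == "positive":
            signs[i] = 1
        elif cfg.trend_mode == "negative":
            signs[i] = -1
        elif cfg.trend_mode == "random":
            signs[i] = 1 if rng.random() < 0.5 else -1
        else:
            raise ValueError(f"unknown trend_mode {cfg.trend_mode!r}")

    # --- barrages and events ----------------------------------------------
    R = cfg.n_recordings
    T = cfg.recording_duration_min * 60.0
    recordings = [Recording(f"r{r}", cfg.recording_duration_min) for r in range(R)]
    mean_gap = max(60.0 / cfg.barrage_rate_per_min - cfg.min_barrage_gap_s, 0.5)
    barrages: list[Barrage] = []
    sizes: dict[str, float] = {}
    events: list[TransmissionEvent] = []
    frame_dt = 1.0 / cfg.frame_rate_hz
    dur_frames = max(2, int(round(cfg.gcamp_decay_s / frame_dt)))
    # expected rendered charge of a unit-size barrage, pC
    # expected rendered charge per second of a unit-size barrage, pC/s
    charge_rate = (
        cfg.hidden_input_rate_per_s * cfg.epsc_amp_pA * cfg.epsc_decay_ms / 1000.0
    )

    def ramp(i: int, r: int) -> float:
        if signs[i] == 0 or R < 2:
            return 1.0
        return 1.0 + signs[i] * cfg.trend_magnitude * (r / (R - 1) - 0.5)

    for r in range(R):
        rec = f"r{r}"
        t = float(rng.exponential(mean_gap))
        k = 0
        while True:
            dur = float(rng.uniform(*cfg.barrage_duration_range_s))
            if t + dur > T:
                break
            size = max(
                cfg.barrage_size_min, float(rng.lognormal(0.0, cfg.barrage_size_sigma))
            )
            bid = f"{rec}_b{k}"
            barrages.append(
                Barrage(
                    barrage_id=bid,
                    recording_id=rec,
                    onset=t,
                    offset=t + dur,
                    charge_pC=size * dur * charge_rate,
                    peak_pA=0.0,
                )
            )
            sizes[bid] = size
            p_recruit = min(1.0, cfg.p_domain_recruit * cfg.freq_scale * size)
            draws = rng.random(n_domains_total)
            # only multi-synapse domains are recruited as units; lone
            # high-release synapses fire out of sync (background only)
            recruited = {
                d
                for d in range(n_domains_total)
                if draws[d] < p_recruit and domain_size[d] >= 2
            }
            for i in range(n):
                in_recruited = membership[i] is not None and membership[i] in recruited
                if in_recruited:
                    p = min(1.0, cfg.p_fire_given_recruit * q[i] * ramp(i, r))
                else:
                    p = min(
                        1.0,
                        cfg.p_background_fire * cfg.freq_scale * size
                        * q[i] * ramp(i, r),
                    )
                if rng.random() < p:
                    amp = (
                        cfg.amplitude_scale
                        * size**cfg.amplitude_charge_beta
                        * float(rng.lognormal(0.0, cfg.amplitude_noise_sigma))
                    )
                    events.append(
                        TransmissionEvent(
                            synapse_id=ids[i],
                            recording_id=rec,
                            onset=float(rng.uniform(t, t + dur)),
                            duration_frames=dur_frames,
                            amplitude=amp,
                            barrage_id=bid,
                        )
                    )
            t += dur + cfg.min_barrage_gap_s + float(rng.exponential(mean_gap))
            k += 1
        # out-of-barrage background events
        windows = [
            (b.onset - 0.5, b.offset + 0.5) for b in barrages if b.recording_id == rec
        ]
        for i in range(n):
            # lone high-release synapses transmit out of sync with the
            # network: most of their activity falls between barrages
            lone = (
                is_high[i]
                and membership[i] is not None
                and domain_size[membership[i]] == 1
            )
            rate = (
                cfg.lone_out_rate_per_min
                if lone
                else cfg.out_of_barrage_rate_per_min
            )
            lam = (
                rate
                * cfg.freq_scale
                * q[i]
                * ramp(i, r)
                * cfg.recording_duration_min
            )
            for _ in range(rng.poisson(min(lam, 50.0))):
                t_ev = float(rng.uniform(0, T))
                if any(lo <= t_ev <= hi for lo, hi in windows):
                    continue
                amp = cfg.amplitude_scale * float(
                    rng.lognormal(0.0, cfg.amplitude_noise_sigma)
                )
                events.append(
                    TransmissionEvent(
                        synapse_id=ids[i],
                        recording_id=rec,
                        onset=t_ev,
                        duration_frames=dur_frames,
                        amplitude=amp,
                        barrage_id=None,
                    )
                )

    events.sort(key=lambda e: (e.recording_id, e.onset, e.synapse_id))
    n_by_barrage: dict[str, int] = {}
    for ev in events:
        if ev.barrage_id is not None:
            n_by_barrage[ev.barrage_id] = n_by_barrage.get(ev.barrage_id, 0) + 1
    for b in barrages:
        b.n_events = n_by_barrage.get(b.barrage_id, 0)

    synapses = [
        Synapse(
            synapse_id=ids[i],
            position=positions[i],
            kind=kinds[i],
            events=[ev for ev in events if ev.synapse_id == ids[i]],
        )
        for i in range(n)
    ]
    experiment = Experiment(
        dendrite_id=dendrite_id,
        tree=tree,
        synapses=synapses,
        recordings=recordings,
        barrages=[replace(b) for b in barrages],
        age=cfg.age,
    )
    compute_frequencies(experiment)
    truth = GroundTruth(
        domain_membership={ids[i]: membership[i] for i in range(n)},
        high_release={ids[i]: bool(is_high[i]) for i in range(n)},
        trend_sign={ids[i]: int(signs[i]) for i in range(n)},
        events=events,
        barrages=barrages,
        barrage_size=sizes,
        propensity={ids[i]: float(q[i]) for i in range(n)},
    )
    return experiment, truth


def generate_cohort(
    seed: int = 0, n_per_group: int = 6
) -> list[tuple[Experiment, GroundTruth]]:
    """The study-sized cohort: n_per_group dendrites per age group
    ("young" P8–10 and "old" P12–13), seeds derived from ``seed``."""
    out = []
    for g, name in enumerate(["young", "old"]):
        for k in range(n_per_group):
            cfg = preset(name, seed=int(seed) * 10007 + g * 1001 + k)
            out.append(generate_experiment(cfg, dendrite_id=f"{name}{k}"))
    return out


def _gcamp_kernel(cfg: GeneratorConfig, dt: float) -> np.ndarray:
    t = np.arange(0.0, cfg.gcamp_decay_s * 6, dt)
    k = (1.0 - np.exp(-t / cfg.gcamp_rise_s)) * np.exp(-t / cfg.gcamp_decay_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def render_traces(
    experiment: Experiment,
    truth: GroundTruth,
    config: GeneratorConfig,
) -> tuple[list[RoiTrace], dict[str, CurrentTrace]]:
    """Render raw observables from the generated events.

    ΔF traces: one per (synapse, recording), events convolved with the
    calcium-indicator kernel plus Gaussian noise.  Somatic current: one
    10 kHz trace per recording, summing an EPSC kernel per event — both the
    imaged synapses' events and the hidden (unimaged) inputs that make up
    each barrage — plus Gaussian noise.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 7919])
    T = cfg.recording_duration_min * 60.0
    dt_f = 1.0 / cfg.frame_rate_hz
    frames = np.arange(0.0, T, dt_f)
    kernel = _gcamp_kernel(cfg, dt_f)

    roi_traces: list[RoiTrace] = []
    for syn in experiment.synapses:
        for rec in experiment.recordings:
            x = np.zeros(len(frames))
            for ev in syn.events:
                if ev.recording_id != rec.recording_id:
                    continue
                i0 = int(np.searchsorted(frames, ev.onset))
                seg = kernel[: len(x) - i0]
                x[i0 : i0 + len(seg)] += ev.amplitude * seg
            x += rng.normal(0.0, cfg.trace_noise_sd, size=len(x))
            roi_traces.append(
                RoiTrace(
                    roi_id=syn.synapse_id,
                    times=frames.copy(),
                    values=x,
                    recording_id=rec.recording_id,
                )
            )

    fs = 10_000.0
    dt_c = 1.0 / fs
    t_c = np.arange(0.0, T, dt_c)
    tau = cfg.epsc_decay_ms / 1000.0
    ek = np.exp(-np.arange(0.0, tau * 8, dt_c) / tau)
    current: dict[str, CurrentTrace] = {}
    for rec in experiment.recordings:
        y = rng.normal(0.0, cfg.current_noise_pA, size=len(t_c))
        times = [
            ev.onset for ev in truth.events if ev.recording_id == rec.recording_id
        ]
        amps = [cfg.epsc_amp_pA] * len(times)
        for b in truth.barrages:
            if b.recording_id != rec.recording_id:
                continue
            n_hidden = rng.poisson(
                cfg.hidden_input_rate_per_s
                * (b.offset - b.onset)
                * truth.barrage_size[b.barrage_id]
            )
            # an early burst plus sustained input: the compound current
            # rises fast at barrage onset and persists across the window
            n_burst = rng.binomial(n_hidden, 0.35)
            dur_b = b.offset - b.onset
            times.extend(b.onset + 0.12 * dur_b * rng.random(n_burst))
            times.extend(b.onset + dur_b * rng.random(n_hidden - n_burst))
            amps.extend(
                cfg.epsc_amp_pA * rng.lognormal(0.0, 0.3, size=n_hidden)
            )
        for t0, a in zip(times, amps):
            i0 = int(np.searchsorted(t_c, t0))
            seg = ek[: len(y) - i0]
            y[i0 : i0 + len(seg)] -= a * seg  # inward = negative
        current[rec.recording_id] = CurrentTrace(
            times=t_c.copy(), values=y, recording_id=rec.recording_id
        )
    return roi_traces, current
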