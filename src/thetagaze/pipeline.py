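"""End-to-end orchestration: synth -> classify -> mask -> spectral -> align ->
context -> stats, with a reproducible report.

A *study* is a set of sessions (one per synthetic participant).  For each
session the pipeline classifies gaze, builds the IED exclusion mask, computes
z-scored theta band power, rasterizes oculomotor and task-context labels onto
the iEEG timeline, and derives per-channel statistics for every requested
contrast using balanced subsampling.  Channel values are then aggregated
across participants and tested with the restricted permutation engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import align, behavior, eye, ied, spectral, stats, synth
from .session import SessionBundle, slice_by_trials


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 5
    channels_per_participant: tuple = (4, 3, 3, 3, 3)   # 16 channels total
    session_duration_s: float = 168.0                   # 8 trials of 20 s + gaps
    n_trials: int = 8
    cycles: float = 6.0
    band: tuple = (5.0, 8.0)
    n_subsample_iterations: int = 500
    n_permutations: int = 10_000
    power_lock_gain: float = 2.5
    power_lock_condition: str | None = "MC"
    phase_lock: bool = False
    ied_rate_hz: float = 0.05
    contrasts: tuple = (
        "saccade_vs_fixation_MC", "saccade_vs_fixation_VC",
        "saccade_vs_fixation_pooled", "MC_vs_VC",
        "tertile_HP_vs_LP", "magnitude_split_MC", "entropy_split_MC",
        "frequency_split_MC", "boundary_MC", "inner_MC",
        "moving_MC", "stationary_MC", "first_half_MC", "second_half_MC",
        "ppc_saccade_vs_baseline",
    )


def generate_study(config: RunConfig, null=False):
    """One synthetic session per participant; ``null`` disables all injected
    saccade locking (gain 1, no phase reset)."""
    ss = np.random.SeedSequence(config.seed)
    sessions = []
    for p, child in enumerate(ss.spawn(config.n_participants)):
        np_params = synth.NeuralGenParams(
            power_lock_gain=1.0 if null else config.power_lock_gain,
            power_lock_condition=config.power_lock_condition,
            phase_lock=(not null) and config.phase_lock,
            ied_rate_hz=config.ied_rate_hz,
        )
        n_ch = config.channels_per_participant[p % len(config.channels_per_participant)]
        bundle, truth = synth.gen_session(
            seed=int(child.generate_state(1)[0] % 2**31),
            duration_s=config.session_duration_s,
            n_channels=n_ch, n_trials=config.n_trials,
            neural_params=np_params, participant_id=f"P{p + 1}",
        )
        sessions.append((bundle, truth))
    return sessions


# ---------------------------------------------------------------------------
# per-session feature extraction
# ---------------------------------------------------------------------------

def session_features(bundle: SessionBundle, config: RunConfig, seed=0,
                     with_phase=True) -> dict:
    """All per-session quantities the contrast battery consumes."""
    rate = bundle.ieeg.rate
    t_ieeg = bundle.ieeg.times
    n = bundle.ieeg.n_samples

    feats = eye.compute_kinematics(bundle.gaze)
    labels = eye.classify_samples(feats, seed=seed)
    events = eye.events_from_labels(labels.t, labels.label,
                                    bundle.gaze.x, bundle.gaze.y)
    labels = eye.SampleLabels(t=labels.t, label=labels.label, events=events)

    ied_mask = ied.detect_ied(bundle.ieeg)
    any_masked = ied_mask.mask.any(axis=0)

    # theta power restricted to the analysis band's frequency bins
    grid = spectral.default_grid()
    sel = (grid >= config.band[0]) & (grid <= config.band[1])
    stack = spectral.wavelet_power(bundle.ieeg, freqs=grid[sel], cycles=config.cycles)
    stack = spectral.zscore_power(stack, mask=ied_mask.mask)
    theta = spectral.band_power(stack, config.band)     # (n_ch, n)

    # oculomotor state on the iEEG timeline
    gaze_idx = np.searchsorted(bundle.gaze.t, t_ieeg)
    gaze_idx = np.clip(gaze_idx, 0, len(bundle.gaze.t) - 1)
    state = labels.label[gaze_idx]
    sacc = state == "saccade"
    fix = state == "fixation"

    cond = {c: slice_by_trials(bundle, c)["ieeg"] for c in ("MC", "VC")}

    # body context on the iEEG timeline
    speed = behavior.body_speed(bundle.body)
    body_idx = np.clip(np.searchsorted(bundle.body.t, t_ieeg), 0,
                       len(bundle.body.t) - 1)
    in_body = (t_ieeg >= bundle.body.t[0]) & (t_ieeg <= bundle.body.t[-1])
    moving = behavior.moving_mask(speed)[body_idx] & in_body
    boundary = behavior.boundary_mask(bundle.body, bundle.room)[body_idx] & in_body

    # performance tertiles and trial halves
    mc_perf = behavior.trial_detour_errors(bundle.trials, bundle.body)
    tert = behavior.performance_tertiles(mc_perf)
    halves = behavior.trial_half_spans(bundle.trials)

    # windowed saccade counts and scanpath entropy at 4 ms steps (computed
    # only when a requested contrast consumes them)
    need_count = any("frequency_split" in c for c in config.contrasts)
    need_entropy = any("entropy_split" in c for c in config.contrasts)
    wc_t = wc = we_t = we = None
    if need_count:
        wc_t, wc = eye.saccade_count_windows(labels, step_s=0.004)
    if need_entropy:
        we_t, we = eye.scanpath_entropy(bundle.gaze, labels, step_s=0.004)

    out = {
        "bundle": bundle, "labels": labels, "events": events,
        "ied_mask": ied_mask, "any_masked": any_masked,
        "theta": theta, "t_ieeg": t_ieeg, "rate": rate,
        "sacc": sacc, "fix": fix, "cond": cond,
        "moving": moving, "boundary": boundary, "in_body": in_body,
        "tertiles": tert, "halves": halves,
        "win_count": (wc_t, wc), "win_entropy": (we_t, we),
    }
    if with_phase:
        out["phase"] = align.theta_phase(bundle.ieeg, band=config.band)
    return out


def _balanced_diff(theta_ch, mask_a, mask_b, keep, n_iter, seed):
    """Balanced-subsample mean difference (a - b) of one channel's theta."""
    a = theta_ch[mask_a & keep]
    b = theta_ch[mask_b & keep]
    ma, mb, _ = stats.balanced_subsample_means(a, b, n_iterations=n_iter, seed=seed)
    return ma - mb


def session_contrast_values(fs: dict, config: RunConfig, seed=0) -> pd.DataFrame:
    """Per-channel contrast statistics for one session.

    Returns a long DataFrame (channel, contrast, value) of balanced
    mean differences; IED-masked and NaN samples are excluded throughout.
    """
    theta = fs["theta"]
    n_ch = theta.shape[0]
    rng = np.random.default_rng(seed)
    t = fs["t_ieeg"]
    sacc, fix = fs["sacc"], fs["fix"]
    cond = fs["cond"]
    keep_base = ~fs["any_masked"]

    hspans = fs["halves"]
    tert = fs["tertiles"]
    tert_spans = {
        g: tert[tert["tertile"] == g] for g in ("HP", "MP", "LP")
    }
    rows = []

    def add(contrast, ch, value):
        rows.append({"channel": ch, "contrast": contrast, "value": value})

    def wants(prefix):
        return any(c.startswith(prefix) or prefix in c for c in config.contrasts)

    # median split of saccade displacement, per condition
    ev = fs["events"]
    sev = ev[ev["kind"] == "saccade"]
    large_mask_by_cond = {}
    for c in ("MC", "VC") if wants("magnitude_split") else ():
        onset_in = cond[c][np.clip(
            np.round((sev["onset_s"].values - t[0]) * fs["rate"]).astype(int),
            0, len(t) - 1)]
        vals = sev["displacement"].values.copy()
        vals[~onset_in] = np.nan
        high = eye.median_split(vals)
        m_large = np.zeros(len(t), dtype=bool)
        m_small = np.zeros(len(t), dtype=bool)
        for (_, r), h, ok in zip(sev.iterrows(), high, onset_in):
            if not ok:
                continue
            span = (t >= r["onset_s"]) & (t < r["offset_s"])
            (m_large if h else m_small)[span] = True
        large_mask_by_cond[c] = (m_large, m_small)

    # windowed splits: map window centers to iEEG samples
    def window_split_masks(wt, wv, c):
        ci = cond[c][np.clip(np.round((wt - t[0]) * fs["rate"]).astype(int),
                             0, len(t) - 1)]
        ok = ci & np.isfinite(wv)
        high = np.zeros(len(wt), dtype=bool)
        high[ok] = eye.median_split(wv[ok])
        low = ok & ~high
        hi_idx = np.clip(np.round((wt[high & ok] - t[0]) * fs["rate"]).astype(int),
                         0, len(t) - 1)
        lo_idx = np.clip(np.round((wt[low] - t[0]) * fs["rate"]).astype(int),
                         0, len(t) - 1)
        mh = np.zeros(len(t), dtype=bool)
        ml = np.zeros(len(t), dtype=bool)
        mh[hi_idx] = True
        ml[lo_idx] = True
        return mh, ml

    for ch in range(n_ch):
        th = theta[ch]
        keep = keep_base & np.isfinite(th)
        sd = int(rng.integers(2**31))

        def bdiff(ma, mb, s_off=0):
            return _balanced_diff(th, ma, mb, keep,
                                  config.n_subsample_iterations, sd + s_off)

        for c in ("MC", "VC"):
            add(f"saccade_vs_fixation_{c}", ch,
                bdiff(sacc & cond[c], fix & cond[c]))
        add("saccade_vs_fixation_pooled", ch, bdiff(sacc, fix, 1))

        # performance tertiles: mean theta during saccades per tertile
        if wants("tertile"):
            tmeans = {}
            for g, spans in tert_spans.items():
                m = behavior.spans_to_mask(spans, t)
                sel = sacc & m & keep
                tmeans[g] = np.nanmean(th[sel]) if sel.any() else np.nan
                # saccade-vs-fixation within tertile
                if sel.any() and (fix & m & keep).any():
                    add(f"tertile_{g}_sacc_vs_fix", ch, bdiff(sacc & m, fix & m, 2))
            for g in ("HP", "MP", "LP"):
                add(f"tertile_{g}_saccade_theta", ch, tmeans[g])

        # magnitude split
        for c in large_mask_by_cond:
            ml_, ms_ = large_mask_by_cond[c]
            if (ml_ & keep).any() and (ms_ & keep).any():
                add(f"magnitude_split_{c}", ch, bdiff(ml_, ms_, 3))

        # saccade-frequency and entropy splits
        for name, (wt, wv) in (("frequency", fs["win_count"]),
                               ("entropy", fs["win_entropy"])):
            if wt is None:
                continue
            for c in ("MC", "VC"):
                mh, ml_ = window_split_masks(np.asarray(wt),
                                             np.asarray(wv, dtype=float), c)
                if (mh & keep).any() and (ml_ & keep).any():
                    add(f"{name}_split_{c}", ch, bdiff(mh, ml_, 4))

        # spatial / movement contexts: saccade-vs-fixation within context
        ctx = {"boundary": fs["boundary"], "inner": fs["in_body"] & ~fs["boundary"],
               "moving": fs["moving"], "stationary": fs["in_body"] & ~fs["moving"]}
        for cname, cm in ctx.items():
            if not wants(cname):
                continue
            for c in ("MC", "VC"):
                m = cm & cond[c]
                if (sacc & m & keep).any() and (fix & m & keep).any():
                    add(f"{cname}_{c}", ch, bdiff(sacc & m, fix & m, 5))

        # trial halves
        for half in ("first", "second") if wants("half") else ():
            for c in ("MC", "VC"):
                spans = hspans[(hspans["half"] == half) & (hspans["condition"] == c)]
                m = behavior.spans_to_mask(spans, t)
                if (sacc & m & keep).any() and (fix & m & keep).any():
                    add(f"{half}_half_{c}", ch, bdiff(sacc & m, fix & m, 6))

        # PPC: saccade window minus baseline window
        if "phase" in fs:
            try:
                res = align.ppc_timecourse(fs["phase"][ch], t, fs["events"],
                                           fs["rate"],
                                           mask=fs["ied_mask"].mask[ch])
                add("ppc_saccade_vs_baseline", ch,
                    res.saccade_window_mean - res.baseline_window_mean)
            except ValueError:
                pass

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-level aggregation and testing
# ---------------------------------------------------------------------------

def analyze_study(sessions, config: RunConfig) -> dict:
    """Run the full contrast battery over a list of SessionBundles.

    ``sessions`` may contain bundles or (bundle, truth) pairs.  Returns the
    run report: per-contrast StatResults plus per-stage QC counts.
    """
    ss = np.random.SeedSequence(config.seed + 1)
    children = ss.spawn(len(sessions))
    frames = []
    qc = []
    for i, s in enumerate(sessions):
        bundle = s[0] if isinstance(s, tuple) else s
        sd = int(children[i].generate_state(1)[0] % 2**31)
        fs = session_features(bundle, config, seed=sd,
                              with_phase="ppc_saccade_vs_baseline" in config.contrasts)
        vals = session_contrast_values(fs, config, seed=sd)
        vals["participant"] = bundle.participant_id
        frames.append(vals)
        qc.append({
            "participant": bundle.participant_id,
            "n_channels": bundle.ieeg.n_channels,
            "n_saccades": int((fs["events"]["kind"] == "saccade").sum()),
            "ied_excluded_fraction": [float(f) for f in
                                      fs["ied_mask"].excluded_fraction],
        })
    values = pd.concat(frames, ignore_index=True)

    spec = stats.PermutationSpec(n_permutations=config.n_permutations,
                                 seed=config.seed + 2)
    report = {"config": asdict(config), "qc": qc, "contrasts": {}}

    def test_one(name, direct=None):
        df = values[values["contrast"] == (direct or name)].dropna(subset=["value"])
        if df.empty:
            return None
        res = stats.signflip_test(df["value"].values, df["participant"].values, spec)
        return res

    # single-condition and context contrasts: one-sample vs 0
    simple = [c for c in values["contrast"].unique()
              if not c.startswith("tertile_") or c.endswith("sacc_vs_fix")]
    for name in simple:
        res = test_one(name)
        if res is not None:
            report["contrasts"][name] = _result_dict(res)

    # MC vs VC: difference of saccade-fixation differences
    pv = values.pivot_table(index=["participant", "channel"],
                            columns="contrast", values="value")
    if {"saccade_vs_fixation_MC", "saccade_vs_fixation_VC"} <= set(pv.columns):
        sub = pv.dropna(subset=["saccade_vs_fixation_MC", "saccade_vs_fixation_VC"])
        res = stats.paired_label_test(
            sub["saccade_vs_fixation_MC"].values,
            sub["saccade_vs_fixation_VC"].values,
            sub.index.get_level_values("participant").values, spec)
        report["contrasts"]["MC_vs_VC"] = _result_dict(res)

    # tertile pairwise comparisons on saccade theta, FDR corrected
    tert_cols = [f"tertile_{g}_saccade_theta" for g in ("HP", "MP", "LP")]
    if set(tert_cols) <= set(pv.columns):
        sub = pv.dropna(subset=tert_cols)
        blocks = sub.index.get_level_values("participant").values
        pairs = [("HP", "LP"), ("MP", "LP"), ("HP", "MP")]
        results = {}
        for a, b in pairs:
            results[f"tertile_{a}_vs_{b}"] = stats.paired_label_test(
                sub[f"tertile_{a}_saccade_theta"].values,
                sub[f"tertile_{b}_saccade_theta"].values, blocks, spec)
        qs = stats.fdr_correct([r.p for r in results.values()])
        for (name, res), q in zip(results.items(), qs):
            res.q = float(q)
            report["contrasts"][name] = _result_dict(res)

    return report


def _result_dict(res: stats.StatResult) -> dict:
    return {
        "t": res.observed_t, "p": res.p, "q": res.q,
        "n_channels": res.n_channels, "scheme": res.scheme,
        "exhaustive": res.exhaustive, "min_attainable_p": res.min_attainable_p,
        "significant": bool(res.p <= 0.05),
    }


def run_pipeline(config: RunConfig, sessions=None, out_path=None) -> dict:
    """Synthesize (unless sessions are given), analyze, and optionally write
    stats_report.json.  Deterministic under ``config.seed``."""
    if sessions is None:
        sessions = generate_study(config)
    report = analyze_study(sessions, config)
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(report: dict, out_dir, fs: dict | None = None):
    """Bar-with-channel-dots panels for each contrast; optional peri-saccade
    trace and time x frequency heatmap when session features are supplied."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    contrasts = report.get("contrasts", {})
    if not contrasts:
        fig, ax = plt.subplots()
        ax.text(0.5, 0.5, "empty report", ha="center")
        p = out / "contrasts.png"
        fig.savefig(p)
        plt.close(fig)
        return [p]

    names = list(contrasts)
    ts = [contrasts[n]["t"] for n in names]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(names)), ts)
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel("across-channel t")
    fig.tight_layout()
    p = out / "contrasts.png"
    fig.savefig(p)
    plt.close(fig)
    written.append(p)

    if fs is not None:
        tensor = align.epoch_power(fs["theta"][0], fs["t_ieeg"], fs["events"],
                                   fs["rate"], mask=fs["ied_mask"].mask[0])
        fig, ax = plt.subplots()
        ax.plot(tensor.time_ms, tensor.mean_trace())
        ax.axvline(0, ls=":", color="k")
        ax.set_xlabel("time from saccade onset (ms)")
        ax.set_ylabel("z theta power")
        p = out / "peri_saccade_trace.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
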