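#!/usr/bin/env python
"""Specificity controls and correlation-based maps on coupled sessions.

(a) time-mirrored and between-session-swapped event arrays, used as GLM
    regressors on coupled data, must produce no suprathreshold activation
    while the veridical regressor recovers the planted compartment;
(b) a seed-based correlation map (r > 0.5, clusters > 300 voxels counted)
    from a small cortical seed;
(c) the calcium-informed map: event-locked voxel responses correlated with
    an ROI reference (r > 0.8, clusters < 70 voxels removed) plus the
    voxelwise time-to-peak map;
(d) lagged cross-correlation of two noisy copies of the same calcium trace
    (the dual-fiber / calcium-vs-LFP style check).

Writes results/05_controls.json.
"""

import json
from pathlib import Path

import numpy as np

from swbold import detect, glm as G
from swbold.correlate import (
    calcium_informed_map,
    cross_correlate,
    mirror_events,
    regress_out,
    seed_correlation_map,
    swap_events,
)
from swbold.preprocess import standard_preprocess
from swbold.simulate import (
    BoldSimConfig,
    default_hrf_params,
    preset,
    sample_hrf_kernel,
    simulate_bold_session,
    simulate_calcium_trace,
)
from swbold.types import EventArray

RESULTS = Path(__file__).parents[1] / "results"


def coupled_session(seed: int, n_volumes: int = 1205):
    sim = simulate_calcium_trace(preset("ogb1", duration_s=float(n_volumes), seed=seed))
    bsim = simulate_bold_session(
        BoldSimConfig(n_volumes=n_volumes, grid_shape=(10, 10, 4), seed=seed + 100),
        sim.truth_events,
    )
    bold = G.preprocess_bold(bsim.session)
    events = detect.detect_events(standard_preprocess(sim.trace))
    onsets = events.onsets_s - 5.0
    keep = onsets >= 0
    ev = EventArray(onsets[keep],
                    np.minimum(events.durations_s[keep], bold.duration_s - onsets[keep]),
                    bold.duration_s)
    return sim, bsim, bold, ev


def specificity_controls(n_runs: int = 8) -> dict:
    kernel = sample_hrf_kernel(default_hrf_params(), 1.0, peak_pct=1.0)
    sens, control_voxels = [], []
    prev = None
    for run in range(1, n_runs + 1):
        _, bsim, bold, ev = coupled_session(run)
        variants = {"true": ev, "mirror": mirror_events(ev)}
        if prev is not None:
            variants["swap"] = swap_events(prev, bold.duration_s)
        for tag, e in variants.items():
            sw = detect.binarize_to_tr(e, bold.tr_s, bold.n_volumes)
            onv = np.floor(e.onsets_s / bold.tr_s).astype(int)
            reg = G.make_regressor(sw, kernel, model="impulse", onset_volumes=onv)
            out = G.t_test_map(G.fit_glm(bold, reg[:, None]), [1.0], correction="fwe")
            if tag == "true":
                sens.append(float(out["supra"][bsim.cortical_mask].mean()))
            else:
                control_voxels.append(int(out["supra"].sum()))
        prev = ev
    return {
        "true_sensitivity_mean": float(np.mean(sens)),
        "control_suprathreshold_voxels": control_voxels,
        "control_runs_with_any_activation": int(np.sum(np.array(control_voxels) > 0)),
    }


def correlation_maps() -> dict:
    """Correlation mapping in two CNR regimes.

    At the default CNR (0.17% response vs 0.5% thermal noise) single-voxel
    timecourse correlations are bounded near r ~ 0.1, so the published
    thresholds (0.5 seed-based, 0.8 calcium-informed) find nothing -- the
    thresholds presuppose the shared-physiological-signal regime of real
    recordings. A low-noise session demonstrates the machinery in that
    regime.
    """
    out = {}
    # default-CNR seed map: the threshold is out of reach by construction
    _, bsim, bold, ev = coupled_session(31)
    seed_mask = bsim.cortical_mask & False
    seed_mask[tuple(np.argwhere(bsim.cortical_mask)[:8].T)] = True
    smap = seed_correlation_map(bold, seed_mask, r_thresh=0.5, min_cluster=300)
    out["seed_clusters_default_cnr"] = smap.n_clusters

    # shared-signal regime: noise well below the slow-wave BOLD fluctuation
    rng = np.random.default_rng(33)
    onsets, t = [], 12.0
    while t < 1160.0:
        onsets.append(t)
        t += 3.0 + rng.exponential(2.5)
    events = EventArray(np.array(onsets), np.full(len(onsets), 1.3), 1200.0)
    # grid large enough that the coupled compartment (40% of voxels)
    # exceeds the >300-voxel cluster rule
    bsim2 = simulate_bold_session(
        BoldSimConfig(n_volumes=1200, grid_shape=(14, 14, 6),
                      noise_sd_pct=0.08, seed=34),
        events,
    )
    bold2 = G.preprocess_bold(bsim2.session)
    ons = events.onsets_s - 5.0
    ev2 = EventArray(ons[ons >= 0], np.full((ons >= 0).sum(), 1.3),
                     bold2.duration_s)
    seed2 = bsim2.cortical_mask & False
    seed2[tuple(np.argwhere(bsim2.cortical_mask)[:8].T)] = True
    smap2 = seed_correlation_map(bold2, seed2, r_thresh=0.5, min_cluster=300)
    out["seed_clusters_gt300"] = smap2.n_clusters
    out["seed_supra_cortical_fraction"] = float(
        smap2.supra_mask[bsim2.cortical_mask].mean())

    # residualizing the slow-wave regressor removes the seed coupling
    kernel = sample_hrf_kernel(default_hrf_params(), 1.0, peak_pct=1.0)
    sw = detect.binarize_to_tr(ev2, bold2.tr_s, bold2.n_volumes)
    onv = np.floor(ev2.onsets_s / bold2.tr_s).astype(int)
    reg = G.make_regressor(sw, kernel, model="impulse", onset_volumes=onv)
    resid = regress_out(bold2, reg)
    smap3 = seed_correlation_map(resid, seed2, r_thresh=0.5, min_cluster=300)
    out["seed_clusters_after_regress_out"] = smap3.n_clusters

    # calcium-informed map needs events sparse enough for clean
    # event-locked averages
    rng = np.random.default_rng(35)
    onsets, t = [], 15.0
    while t < 1760.0:
        onsets.append(t)
        t += 12.0 + rng.exponential(6.0)
    events3 = EventArray(np.array(onsets), np.full(len(onsets), 1.3), 1800.0)
    bsim3 = simulate_bold_session(
        BoldSimConfig(n_volumes=1800, grid_shape=(10, 10, 4),
                      noise_sd_pct=0.08, seed=36),
        events3,
    )
    roi = bsim3.cortical_mask & False
    roi[tuple(np.argwhere(bsim3.cortical_mask)[:8].T)] = True
    cmap, ttp = calcium_informed_map(bsim3.session, events3, roi,
                                     r_thresh=0.8, min_cluster=70)
    out["calcium_informed_surviving_voxels"] = int(cmap.supra_mask.sum())
    out["calcium_informed_ttp_median_s"] = (
        float(np.nanmedian(ttp[cmap.supra_mask])) if cmap.supra_mask.any() else None
    )

    from swbold.preprocess import downsample_by_averaging
    from swbold.simulate import preset as _preset, simulate_calcium_trace as _sim

    tr = downsample_by_averaging(_sim(_preset("ogb1", duration_s=600.0, seed=37)).trace, 20)
    rng = np.random.default_rng(0)
    other = tr.copy_with(tr.values + rng.normal(0, 0.05, tr.n_samples))
    _, _, peak_lag, peak_r = cross_correlate(tr, other, max_lag_s=1.0)
    out["dual_trace_xcorr_peak_lag_s"] = peak_lag
    out["dual_trace_xcorr_peak_r"] = peak_r
    return out


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ctrl = specificity_controls()
    print("specificity controls:")
    print(f"  true regressor: mean sensitivity {ctrl['true_sensitivity_mean']:.3f}")
    print(f"  mirrored/swapped regressors: suprathreshold voxels per run "
          f"{ctrl['control_suprathreshold_voxels']} "
          f"({ctrl['control_runs_with_any_activation']} runs with any)")

    corr = correlation_maps()
    print("\ncorrelation analyses:")
    print(f"  seed map at default CNR: {corr['seed_clusters_default_cnr']} "
          f"cluster(s) -- the r>0.5 threshold presupposes shared signal well "
          f"above thermal noise")
    print(f"  seed map, shared-signal regime: {corr['seed_clusters_gt300']} "
          f"cluster(s) >300 voxels, covering "
          f"{100 * corr['seed_supra_cortical_fraction']:.0f}% of the coupled "
          f"compartment; after regressing out the slow-wave timecourse: "
          f"{corr['seed_clusters_after_regress_out']} cluster(s)")
    print(f"  calcium-informed map: {corr['calcium_informed_surviving_voxels']} "
          f"voxels at r>0.8 (clusters <70 removed), TTP median "
          f"{corr['calcium_informed_ttp_median_s']} s")
    print(f"  dual-trace cross-correlation: peak r={corr['dual_trace_xcorr_peak_r']:.3f} "
          f"at lag {corr['dual_trace_xcorr_peak_lag_s'] * 1000:.0f} ms")

    (RESULTS / "05_controls.json").write_text(json.dumps({**ctrl, **corr}, indent=1))
    print(f"wrote {RESULTS}/05_controls.json")


if __name__ == "__main__":
    main()
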