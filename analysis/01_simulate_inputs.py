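#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/sim/: a baseline ROI-trace table (20 neurons, 10 min),
a texture-session trace table with planted NTS/FTS selectivity plus its
contact schedule and ground-truth labels, a whisking session (whisking
magnitude at 30 fps, whole-field trace at 10 fps, planted gain/delay), a
longitudinal spine table with its per-protrusion ground truth, and a
translated frame pair as a TIFF stack.
"""

import argparse
from pathlib import Path

import pandas as pd

from cortexcal import pipeline_io as pio
from cortexcal import synthgen as sg


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # baseline population: spontaneous activity only
    cfg = sg.PopulationConfig(n_neurons=20, duration_s=600.0, seed=args.seed)
    F, events = sg.generate_population(cfg)
    pio.write_trace_table(out / "baseline_traces.tsv", F, cfg.fps)
    events.to_csv(out / "baseline_truth_events.tsv", sep="\t", index=False)

    # texture session: planted 30% NTS / 5% FTS, 10 contacts per texture
    sel = sg.make_selectivity(100, 0.30, 0.05, amplitude=0.25, seed=args.seed + 1)
    sched = sg.alternating_contact_schedule(10)
    tcfg = sg.PopulationConfig(n_neurons=100, duration_s=150.0, seed=args.seed + 2)
    Ft, _ = sg.generate_texture_session(sel, sched, tcfg)
    pio.write_trace_table(out / "texture_traces.tsv", Ft, tcfg.fps)
    pio.write_interval_table(out / "texture_schedule.tsv", sched.to_frame())
    sel.to_frame().to_csv(out / "texture_truth_labels.tsv", sep="\t", index=False)

    # whisking session: planted gain 0.5, delay 0.3 s
    bouts = sg.regular_bout_schedule(30, bout_s=2.0, gap_s=4.0)
    ses = sg.generate_whisking_session(
        bouts, gain=0.5, delay_s=0.3, noise_sd=0.05, duration_s=200.0, seed=args.seed + 3
    )
    pd.DataFrame({"magnitude": ses["whisking"]}).to_csv(
        out / "whisking_magnitude.tsv", sep="\t", index=False
    )
    pd.DataFrame({"ca_wf": ses["ca_wf"]}).to_csv(out / "ca_wf.tsv", sep="\t", index=False)
    pd.DataFrame([ses["truth"] | {"bout_onsets_s": None}]).to_csv(
        out / "whisking_truth.tsv", sep="\t", index=False
    )

    # spine history: 4 sessions with re-emergence near eliminated sites
    scfg = sg.SpineHistoryConfig(
        n_sessions=4, n_spines_initial=180, p_eliminate=0.10, p_form=0.08,
        reemergence_fraction=0.32, seed=args.seed + 4,
    )
    table, truth = sg.generate_spine_history(scfg)
    pio.write_spine_table(out / "spine_table.tsv", table)
    truth.to_csv(out / "spine_truth.tsv", sep="\t", index=False)

    # frame pair with a planted (3, 4)-pixel shift
    fa, fb = sg.generate_frame_pair((3, 4), noise_sd=0.01, seed=args.seed + 5)
    pio.write_stack(out / "frame_pair.tif", [fa, fb])

    print(f"simulated inputs written to {out}/")
    print(f"  baseline: {F.shape[0]} neurons x {F.shape[1]} frames, {len(events)} events")
    print(f"  texture:  {Ft.shape[0]} neurons, {len(sched.contacts)} contacts")
    print(f"  whisking: {len(bouts)} bouts, gain 0.5, delay {ses['truth']['delay_s']} s")
    print(f"  spines:   {table.protrusion_id.nunique()} protrusions x 4 sessions")


if __name__ == "__main__":
    main()
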