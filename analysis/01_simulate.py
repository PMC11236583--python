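#!/usr/bin/env python
"""Build the study materials: contour audio, session plan, one MEG-like session.

Writes under results/01_simulate/:
  contour_SLOW.wav / contour_FAST.wav   PURR-resynthesized prosodic contours
  f0_SLOW.tsv / f0_FAST.tsv             the underlying F0 tracks
  session_events.tsv                    a 300-trial balanced session timeline

One simulated subject (smoke scale) is written under scratch/01_simulate/
(array container + JSON sidecar + events TSV).
"""

from pathlib import Path

from deltrain import simulate as sim
from deltrain import stimuli

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulate"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for cond in (stimuli.SLOW, stimuli.FAST):
        stimuli.write_f0_tsv(
            stimuli.repeated_contour_track(cond, sample_rate=250.0),
            OUT / f"f0_{cond}.tsv",
        )
        track = stimuli.repeated_contour_track(cond, sample_rate=1000.0)
        wave = stimuli.synthesize_purr(track.shifted(-55.0), 22050.0)
        stimuli.write_wav(wave, OUT / f"contour_{cond}.wav", 22050)
        print(
            f"{cond}: contour {stimuli.CONTOUR_MS[cond]:.0f} ms, "
            f"cycle {stimuli.cycle_duration_ms(cond):.0f} ms "
            f"({stimuli.cycle_rate_hz(cond):.3f} Hz), "
            f"F0 {track.f0.min():.0f}-{track.f0.max():.0f} Hz"
        )

    plan = stimuli.generate_session_plan(300, seed=0)
    stimuli.schedules_to_events_tsv(plan, OUT / "session_events.tsv")
    cells = [s.cell for s in plan]
    print(f"session: {len(plan)} trials, "
          f"{ {c: cells.count(c) for c in stimuli.CELLS} }")

    cfg = sim.SimConfig(n_subjects=2, n_trials=40, seed=0)
    model = sim.build_sensor_model(seed=cfg.seed)
    rec, truth = sim.simulate_subject(
        cfg, sim.generate_plan_for(cfg, 0), model, sim.subject_seeds(cfg.seed, 1)[0]
    )
    scratch = OUT.parent.parent / "scratch" / "01_simulate"
    scratch.mkdir(parents=True, exist_ok=True)
    sim.save_recording(rec, scratch / "sub-00")
    print(
        f"sub-00: {rec.data.shape[0]} channels x {rec.n_samples} samples "
        f"({rec.n_samples / rec.sample_rate:.0f} s), "
        f"{len(truth.omission_trials)} omission trials"
    )


if __name__ == "__main__":
    main()
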