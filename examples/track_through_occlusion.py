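"""Keep an animal's identity through a scripted occlusion.

Two cows walk past each other; the far one is hidden for 5 frames at the
crossing.  The two-stage matcher parks the lost track in the stranding
area, drifts it by its motion vector, and re-attaches the original id when
the cow reappears.  The plain greedy baseline hands out a fresh id instead.
"""

from herdtrack import TrackerConfig, evaluate, generate, preset, run_tracker

scenario = generate(preset("crossing", occlusion_gap=5))
print(f"scenario: 2 targets, {scenario.config.n_frames} frames, "
      f"target 2 hidden for {scenario.config.occlusion_gap} frames")

for label, cfg in [("two-stage", TrackerConfig()),
                   ("greedy-only", TrackerConfig(stage2_enabled=False))]:
    result = run_tracker(scenario.detections, cfg)
    report = evaluate(scenario.gt, result)
    ids = sorted({d.id for d in result})
    print(f"{label:>12}: identities used {ids}, "
          f"id switches {report.idsw}, MOTA {report.mota:.3f}")

# Expected: the two-stage tracker uses exactly 2 identities with 0
# switches; the baseline needs a 3rd identity and books 1 switch.
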