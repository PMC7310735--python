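"""Simulate one subject's sessions and round-trip them through disk.

Generates a training session (5-minute rest) and an exposure session
(demo + 16 one-minute clips with arousal ratings + final rest), writes
them as CSV + JSON sidecar, and reads them back.
"""

from pathlib import Path
from tempfile import mkdtemp

from anxio import SimulationConfig, generate_cohort, read_session, write_session

cfg = SimulationConfig(n_subjects=1, seed=7)
[(subject, truth)] = generate_cohort(cfg)

out = Path(mkdtemp())
for kind in ("training", "exposure"):
    sess = subject.session(kind)
    path = write_session(sess.layout, sess.records, out / f"{subject.subject_id}_{kind}.csv")
    layout, records = read_session(path)
    n = len(records["ecg"].samples)
    print(f"{kind:9s} {layout.duration:7.0f} s  {len(layout.segments):2d} segments "
          f"{n:7d} samples/channel -> {path.name}")

print("ratings (after clip, value 1-4):", truth.ratings)
print("latently high clips:", sorted(c for c, l in truth.clip_levels.items() if l == "high"))
# Each row of the CSV is one 10 ms tick; the ratings drive the subjective
# (SB) labeling approach, the latent clip levels drive the HR/EDA approaches.
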