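"""Generate a synthetic viewing session and inspect its structure.

Builds a 14-channel, 128 Hz recording with a 15 s baseline followed by
five short advertisements whose band-power signatures depend on the
1-5 liking rating, then writes the canonical CSV + XML artifacts.
"""

from pathlib import Path

from adlike import generate_session, write_recording, write_session

out = Path("scratch_example")
out.mkdir(exist_ok=True)

rec, session = generate_session(ratings=[1, 2, 3, 4, 5], seed=42)
write_recording(rec, out / "recording.csv", out / "baseline.csv")
write_session(session, out / "session.xml")

print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"({rec.duration_s:.1f} s at {rec.sampling_rate:.0f} Hz)")
print(f"baseline:  {rec.baseline.shape[1] / rec.sampling_rate:.0f} s")
for v in session.videos:
    print(f"  {v.video_id}: {v.start_s:6.1f}-{v.end_s:6.1f} s  rating {v.rating}")
# Each video segment's alpha/occipital band amplitudes follow its rating's
# multipliers, which is the structure the classifier later recovers.
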