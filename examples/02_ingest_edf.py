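"""Ingest a high-density-net EDF: read, montage-select, resample, cut.

Writes a 128-channel synthetic recording to EDF, reads it back, reduces
it to the standard 19-channel 10-20 montage, and extracts the analysis
segment.  The printed labels are the canonical montage order that fixes
feature indexing downstream.
"""

from pathlib import Path
import tempfile

import eegnld

spec = eegnld.CohortSpec(n_channels=128, duration_s=8.0, seed=3)
rec = eegnld.generate_recording("HRA-", 3.5, spec, 11, age_months=9.0)
path = Path(tempfile.mkdtemp()) / "net128.edf"
eegnld.write_fixture_edf(rec, path)

raw = eegnld.read_edf(path)
print(f"read {raw.n_channels} channels at {raw.fs:g} Hz, {raw.duration_s:g} s")

clean = eegnld.preprocess(raw, duration_s=4.0)
print(f"after preprocessing: {clean.n_channels} channels, "
      f"{clean.fs:g} Hz, {clean.duration_s:g} s")
print("montage order:", ", ".join(clean.channel_labels))
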