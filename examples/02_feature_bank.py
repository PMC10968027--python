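"""Extract the 33-scalar feature bank from a synthetic EEG segment.

Simulates one labeled recording, filters and segments it, and prints a
few features of the first segment's Fz channel with their meaning.
"""

from adhdaid import (FEATURE_NAMES, SimConfig, extract_feature_vector,
                     preprocess_record, segment_record, simulate_record)

record = simulate_record(SimConfig(duration_s=12.0), class_label=1,
                         subject_seed=42)
segments = segment_record(preprocess_record(record))
print(f"{len(segments)} four-second segments from a "
      f"{record.duration_s:.0f} s recording")

fz = segments[0].channels.index("Fz")
vec = dict(zip(FEATURE_NAMES, extract_feature_vector(segments[0].data[fz],
                                                     segments[0].fs)))
print(f"Hjorth activity (variance, uV^2): {vec['hjorth_activity']:.1f}")
print(f"Hjorth mobility (dimensionless):  {vec['hjorth_mobility']:.3f}")
print(f"theta band power (uV^2):          {vec['bp_theta']:.1f}")
print(f"beta band power (uV^2):           {vec['bp_beta']:.1f}")
print(f"alpha/beta power ratio:           {vec['bp_ratio_alpha_beta']:.2f}")
print(f"Shannon entropy:                  {vec['shannon_entropy']:.2f}")
# Activity tracks overall amplitude; mobility the dominant frequency; the
# band powers carry the class effect this generator plants (theta up,
# beta down on fronto-central channels for the ADHD class).
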