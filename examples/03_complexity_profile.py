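"""Exact size/cost accounting of the decremental architecture.

Every quadratic neuron carries 6 coefficients and costs 8 multiplications and
5 additions per forward pass, so the counts follow exactly from the layer
schedule — no profiling run needed.
"""

from eegmdh import DEFAULT_SCHEDULE, profile_schedule

report = profile_schedule(DEFAULT_SCHEDULE)
print(f"schedule: {DEFAULT_SCHEDULE}")
print(report.to_text())
# 166 neurons × 6 coefficients = 996 trainable parameters; one classified
# sample costs 1,328 multiplications + 830 additions = 2,158 operations.

print("\nper-neuron cost:")
print(profile_schedule((1,)).to_text())
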