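"""Generate a synthetic minirhizotron study and inspect its design.

Builds the calibrated default study — 3 ecosystem types x 16 tubes x
3 seasons x 5 depth windows — and prints the design report plus the
per-(ecosystem, depth) sample means, which track the published measured
means (surface rates of ~19-25 m m-2 mo-1 declining to <2 at 71 cm)
while roughly three-quarters of individual windows record no growth.
"""

from rootflux import default_generator_spec, generate_study, validate_design

spec = default_generator_spec(seed=42)
print(f"generator: phi={spec.phi:.1f}, p={spec.power_p}, tube_sd={spec.tube_sd}")

obs = generate_study(spec)
report = validate_design(obs)
print(f"design: {report.summary()}")

means = (
    obs.to_frame()
    .groupby(["ecosystem", "depth_top_cm"], observed=True)["frp_length"]
    .mean()
    .unstack()
    .round(2)
)
print("\nsample mean FRP (m m-2 mo-1) per ecosystem x depth window top (cm):")
print(means)
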