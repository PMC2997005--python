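"""The full anti-correlation target screen, end to end.

Simulates a study with planted microRNA -> gene suppression pairs, runs
quantification, trend classification and the Pearson screen per prediction
scope, and reports how many planted pairs were recovered.
"""

from pancmir import (
    ScreenConfig,
    parse_mirbase_targets,
    parse_targetscan,
    run_study,
    simulate_study,
)

study = simulate_study(seed=42, ct_noise_sd=0.3, effect_size_log2=2.0)
mirbase = parse_mirbase_targets(study.mirbase_file)
targetscan = parse_targetscan(study.targetscan_file)

result = run_study(
    study.ct,
    study.mirna_scheme,
    study.probe_matrix,
    study.probe_map,
    study.mrna_scheme,
    mirbase,
    targetscan,
    config=ScreenConfig(r_squared_min=0.8, use_adjusted_p=False),
)

print("period pairing:", result.period_pairing)
for scope, res in result.scopes.items():
    planted = study.truth.planted_pairs & result.screened_pairs[scope]
    print(
        f"{scope:10s} candidates={res.manifest['family_size']:4d} "
        f"reported={len(res.records):3d} planted recovered={len(planted)}"
    )

top = result.scopes["BOTH"].records.nsmallest(3, "r")
print("\nstrongest negative correlations (intersection scope):")
print(top[["mirna_id", "gene_id", "r", "r_squared", "p_raw", "p_adj"]].to_string(index=False))

# r close to -1 over the three aligned periods marks a predicted target
# whose expression falls exactly as its microRNA rises (or vice versa) —
# the operational signature of suppression used by the screen.
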