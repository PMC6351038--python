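"""Exhaustive mining of feature combinations.

Scores every order-1 and order-2 combination of haplogroup J and CCL5
rs2107538*A carriage, then validates the top combination by label
permutation.
"""

from mitosyn import (
    Feature,
    enumerate_combinations,
    permutation_validate,
    study_feature,
    study_fixture,
)

cohort = study_fixture("ccl5")
features = [Feature.haplogroup("J"), study_feature("ccl5")]
report = enumerate_combinations(cohort, features, max_order=2)

for r in report:
    res = r.result
    flag = "*" if r.significant else " "
    print(f"{flag} {r.combination.name:28s} "
          f"{res.table.a:3d} ({res.freq_case_pct:4.1f}%) vs "
          f"{res.table.c:3d} ({res.freq_control_pct:4.1f}%)  "
          f"P={res.p:.2e}  OR={res.or_value:.2f}")
# The joint combination (21 carrier cases vs 4 carrier controls) is far
# more significant than either component alone — the signature that
# motivates the epistasis analysis.

top = report.results[0]
p_emp = permutation_validate(cohort, top.combination, n_perm=999, seed=1)
print(f"\npermutation P for {top.combination.name}: {p_emp:.4f}")
# The empirical P under case/control label shuffling confirms the
# combination's enrichment is not an artifact of the exact-test convention.
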