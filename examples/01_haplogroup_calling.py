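"""Assign mitochondrial haplogroups from the five diagnostic SNPs.

Builds a three-subject cohort inline and calls each subject's haplogroup
from the alleles at rCRS positions 1719, 7028, 9055, 10398 and 12308, then
summarizes haplogroup frequencies on a reconstructed study cohort.
"""

from mitosyn import call_haplogroup, cohort_from_string, haplogroup_frequencies, study_fixture

TSV = """\
subject_id\tstatus\tsex\tmt_1719\tmt_7028\tmt_9055\tmt_10398\tmt_12308
P1\tcase\tF\tG\tT\tG\tG\tA
P2\tcontrol\tM\tG\tC\tG\tA\tA
P3\tcase\tF\tG\tT\t.\tG\tA
"""

cohort = cohort_from_string(TSV)
for s in cohort:
    call = call_haplogroup(s.mt)
    print(f"{s.subject_id}: {'/'.join(s.mt.as_tuple())} -> {call.label}")
# P1 matches the J-defining haplotype, P2 the H-defining one; P3 has a
# missing marker and cannot be classified (UNKNOWN).

print()
freq = haplogroup_frequencies(study_fixture("ccl5"))
print(freq.round(1))
# Haplogroup J is carried by 15.9% of cases but only 8.6% of controls —
# the enrichment the association analysis quantifies.
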