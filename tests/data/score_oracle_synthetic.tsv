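# Synthetic scoring-parity oracle (hand-derived, frozen).
# Expected per-sample scores under PLINK 1.9 default --score semantics
# (average over 2 x #score-SNPs, missing genotypes mean-imputed at twice the
# effect-allele frequency among observed samples) for the toy fileset defined
# in test_scoring.py: 10 samples, 3 SNPs (s2's effect allele is the cohort's
# a2, exercising dosage flipping).  Values computed once by exact rational
# arithmetic and committed; not recomputed at test time.
sample_id	expected_average_score
i1	0.016666666666666666
i2	0.08333333333333333
i3	0.1398148148148148
i4	-0.008333333333333333
i5	0.016666666666666666
i6	0.08333333333333333
i7	-0.008333333333333333
i8	0.058333333333333334
i9	0.16666666666666666
i10	0.016666666666666666
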