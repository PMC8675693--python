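"""Date a haplotype clade from tract lengths and mutation counts.

Shows the three time estimators: the tract-survival probability used to
reject incomplete lineage sorting, the homozygosity-tract-length age, and
the Poisson maximum-likelihood clade age.
"""

from promoterpop import (
    CladeMutationSummary,
    EvoParams,
    expected_pairwise_differences,
    htl_to_age,
    poisson_ml_tmrca,
    tract_survival_probability,
)

p = EvoParams()

# A 28-kb identical tract surviving since the 550-kyr modern/archaic split
# is essentially impossible without introgression:
surv = tract_survival_probability(28_042, p, 550_000.0)
print(f"P(28-kb tract survives 550 kyr unrecombined) = {surv:.2e}")

# Expected pairwise differences over the 18-kb region across that split:
for t in p.t_split_amh_ah:
    d = expected_pairwise_differences(t, p.mu, 18_000, rounded=True)
    print(f"expected site differences at {t/1000:.0f} kyr: {d:.0f}")

# HTL-based age: an 11-kb mean one-sided homozygosity tract
print(f"age from 11-kb mean HTL (one-sided): {htl_to_age(11_000, p, k=1):,.0f} y")

# Poisson-ML clade age: 9 mutations on 20 star branches of 18 kb
t_hat, (lo, hi) = poisson_ml_tmrca(CladeMutationSummary(9, 20, 18_000, p.mu))
print(f"clade TMRCA: {t_hat:,.0f} y (95% CI {lo:,.0f} - {hi:,.0f})")
# The point estimate equals S / (n L mu); the CI width shrinks as 1/sqrt(S).
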