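"""Per-window diversity statistics from allele counts.

Builds a tiny 4-sequence window with three segregating sites (derived
allele counts 1, 2 and 3) and prints S, the mean pairwise difference
count k-hat, Watterson's theta and Tajima's D. A positive D means an
excess of intermediate-frequency variation relative to the segregating-
site count; here the value is near zero, as expected for a balanced
little site-frequency spectrum.
"""

from tajscan import (SiteAlleleCounts, mean_pairwise_differences, tajimas_d,
                     watterson_theta)

n = 4
sites = [
    SiteAlleleCounts(position=10, allele_counts=(3, 1)),
    SiteAlleleCounts(position=40, allele_counts=(2, 2)),
    SiteAlleleCounts(position=77, allele_counts=(1, 3)),
]

S = sum(1 for s in sites if s.is_segregating)
k_hat = mean_pairwise_differences(sites, n)
theta = watterson_theta(S, n)
d = tajimas_d(S, k_hat, n)

print(f"segregating sites S = {S}")
print(f"mean pairwise differences k_hat = {k_hat:.6f}")
print(f"Watterson theta (per window)    = {theta:.6f}")
print(f"Tajima's D                      = {d.value:.4f}")
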