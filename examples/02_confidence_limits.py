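"""Theoretical confidence limits for Tajima's D.

D is a bounded statistic; its null distribution is approximated by a beta
density on [Dmin, Dmax] rescaled to mean 0 and variance 1. For five
diploid strains (n = 10 sequences) the 95% limits are (-1.733, 1.975):
windows outside that range would be called significant if the genome-wide
distribution were the theoretical one.
"""

from tajscan import beta_confidence_limits

for n in (4, 10, 20):
    lim = beta_confidence_limits(n, coverage=0.95)
    print(f"n = {n:3d}: support [{lim.Dmin:7.3f}, {lim.Dmax:6.3f}]  "
          f"95% limits ({lim.lower:7.3f}, {lim.upper:6.3f})")
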