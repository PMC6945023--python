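"""Allele ages and experienced Ne per frequency class.

Under a population that crashed tenfold, rare (young) alleles mostly
experienced the small recent size while common (old) alleles
experienced the large ancient one.
"""

from stepsfs import Demography, class_summaries

u, L = 1e-8, 1_000_000
# N = 1000 while more than 5 lineages remain (recent), 10000 deeper
decline = Demography.from_levels(
    10, {k: (1_000.0 if k > 5 else 10_000.0) for k in range(2, 11)}
)

print("unfolded report, n=10:")
print(f"{'r':>3} {'mean age':>12} {'sd age':>12} {'experienced Ne':>15}")
for s in class_summaries(decline, u, L):
    print(f"{s.r:>3} {s.mean_age:>12.0f} {s.sd_age:>12.0f} "
          f"{s.mean_experienced_ne:>15.0f}")

print("\nfolded report (minor-allele classes, pd = chance the minor "
      "allele is derived):")
print(f"{'r':>3} {'pd':>6} {'mean age':>12} {'experienced Ne':>15}")
for s in class_summaries(decline, u, L, folded=True):
    print(f"{s.r:>3} {s.pd:>6.3f} {s.mean_age:>12.0f} "
          f"{s.mean_experienced_ne:>15.0f}")

print("\nmean age and experienced Ne rise with frequency: higher-"
      "frequency alleles are older and lived through the larger "
      "ancestral population.")
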