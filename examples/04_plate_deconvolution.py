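"""Deconvolve genotype frequencies from three-media colony counts.

Two strains carry complementary auxotrophies: only heterokaryons grow on
unsupplemented plates, while each supplemented medium additionally grows
one homokaryon class. Subtracting the unsupplemented concentration from
the supplemented ones recovers all three class frequencies.
"""

from cheatkit.platecount import PlateCountTriple, deconvolve_genotypes
from cheatkit.synthetic import simulate_plate_counts

print("Hand-checkable example (concentrations 60 / 50 / 10):")
t = PlateCountTriple(count_inl=60, count_pan=50, count_none=10)
f = deconvolve_genotypes(t)
print(
    f"  inl-homokaryon {f.f_inl_homokaryon:.2f}, "
    f"pan-homokaryon {f.f_pan_homokaryon:.2f}, "
    f"heterokaryon {f.f_heterokaryon:.2f}"
)

truth = (0.55, 0.35, 0.10)
print(f"\nMultinomial sampling at truth {truth}, 4 plates x 400 colonies:")
for seed in range(3):
    counts = simulate_plate_counts(truth, colonies_per_plate=400, n_plates=4, seed=seed)
    est = deconvolve_genotypes(counts)
    print(
        f"  seed {seed}: counts (inl/pan/none) = "
        f"{counts.count_inl}/{counts.count_pan}/{counts.count_none}"
        f"  ->  {tuple(round(x, 3) for x in est.as_tuple())}"
    )

print("\nEstimates scatter around the truth within a few percent at this depth.")
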