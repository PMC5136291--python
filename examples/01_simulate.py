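"""Generate a synthetic input bundle with a planted causal pathway.

Writes VCF genotypes, variant annotations (CADD score + VEP-style
consequence), GMT pathways, BED gene regions, an interaction edge list, a
phenotype/covariate table, and a truth manifest into ./example_output/.
"""

from pathkat import SimSpec, generate_bundle

spec = SimSpec(seed=11, variants_per_gene=(10, 16))
bundle = generate_bundle(spec, "example_output/bundle")

print(f"samples:          {len(bundle.samples)}")
print(f"variants:         {len(bundle.variants)} across {len(bundle.genes)} genes")
print(f"pathways:         {len(bundle.pathways)}")
print(f"causal pathway:   {bundle.truth.causal_pathway}")
print(f"causal genes:     {', '.join(bundle.truth.causal_genes)}")
print(f"causal variants:  {len(bundle.truth.causal_variants)} "
      "(per-allele effects, half negative by design)")
# The trait is causal dosages x effects + 10 'principal component'
# covariates + Gaussian noise; the truth manifest records every effect.
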