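"""Generate a synthetic two-kingdom field experiment and write it as TSVs.

The design mirrors a drought/rewetting trial: 6 control and 6 drought
plots, four plant compartments, weekly sampling over 17 weeks, drought
during weeks 3-8.  Planted effects (kingdom-specific drought shifts,
correlation blocks, a stress factor) are recorded in the manifest.
"""

from droughtnet import synth

design = synth.DesignSpec()
effects = synth.EffectSpec()
data = synth.generate_counts(design, effects, n_bacteria=80, n_fungi=40, seed=1)

print(f"samples:        {data.metadata.shape[0]}")
print(f"bacterial OTUs: {data.bacteria.shape[1]}, fungal OTUs: {data.fungi.shape[1]}")
print(f"library sizes:  {data.bacteria.sum(axis=1).min()}..{data.bacteria.sum(axis=1).max()} reads")
print(f"AMF taxa:       {int(data.taxonomy['amf'].sum())}")

out = synth.write_dataset(data, "scratch/example_dataset")
print(f"wrote {out}/counts_16S.tsv, counts_ITS.tsv, taxonomy.tsv, metadata.tsv")
# The library sizes are drawn log-normally around 25,000 reads, so
# rarefaction to the standard 10,000-read depth never drops a sample.
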