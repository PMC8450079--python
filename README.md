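# yreflank

Analysis toolkit for how basic-leucine-zipper (bZIP) transcription factors of
the AP-1 family — modelled on the yeast factor Yap1 — recognise their DNA
response elements, and how the nucleotides *flanking* those elements modulate
binding and gene expression.

The package implements three connected analyses plus the seeded synthetic-data
generators that feed them:

1. **Protein–DNA contact maps** (`yreflank.contacts`). Hydrogen bonds, salt
   bridges and apolar contacts are detected geometrically in multi-model
   structures; the *contact strength* of a residue pair in a frame is the
   plain count of its contacts, each bond type weighted 1. Contacts joining a
   protein side chain to a DNA base are *specific* (direct readout);
   everything touching a backbone is nonspecific. Per-residue contact
   fingerprints are clustered into conformational substates.
2. **Base-pair-step helical parameters** (`yreflank.helical`). The six step
   parameters (shift, slide, rise / tilt, roll, twist) are extracted with an
   exactly invertible mid-step rotation-vector decomposition. Per-step
   distributions are normalised, classified into the most populated of
   {−, 0, +} states, and compared bound-vs-unbound with a per-step two-sample
   Kolmogorov–Smirnov statistic; the contiguous run of altered steps outward
   from the response-element edge gives the *flank reach* of binding.
3. **Promoter-library flank analysis** (`yreflank.promoters`). Libraries of
   short random promoters with ordinal expression bins are filtered to those
   carrying exactly one response element (YRE1 `TTACTAA`, YRE2 `TTACGTAA`,
   YRE3 `TGACAAA`), grouped by the exact 2-nt or 4-nt flank context of the
   site, and the within-group expression standard deviations of the two
   grouping widths are compared with a Student t-test.

`yreflank.io_formats` reads and writes multi-MODEL PDB, Canal-style `.ser`
series tables, TSV promoter/expression tables and FASTA.
`yreflank.ensemble_utils` provides Kabsch superposition, RMSD series,
windowed average structures and BI/BII backbone classification.
`yreflank.datasets` embeds the six studied 23-mer duplexes and the
12-system manifest.

## Worked example

Group a planted promoter library by flank context at both widths and test
whether the wider context tightens the expression dispersion:

```python
from yreflank.datasets import YRE_MOTIFS
from yreflank.promoters import (dispersion_test, filter_single_instance,
                                group_by_flanks, group_sds)
from yreflank.synthetic import PromoterLibrarySpec, gen_promoter_library

spec = PromoterLibrarySpec(seed=7, flank_design="sampled", n=3000,
                           flank_width=4)
library, truth = gen_promoter_library(spec)
kept, hits, rejected = filter_single_instance(
    library, {"YRE1": YRE_MOTIFS["YRE1"]}, flank_width=4)
g2 = group_by_flanks(kept, hits, 2)
g4 = group_by_flanks(kept, hits, 4)
t, p = dispersion_test(g2, g4)
print(f"promoters kept: {len(kept)} / {len(library)}")
print(f"flank groups:   width 2 -> {len(g2)}, width 4 -> {len(g4)}")
print(f"mean within-group SD: width 2 = {group_sds(g2).mean():.2f}, "
      f"width 4 = {group_sds(g4).mean():.2f}")
print(f"dispersion t-test: t = {t:.1f}, p = {p:.2e}")
```

prints

```
promoters kept: 3000 / 3000
flank groups:   width 2 -> 256, width 4 -> 2941
mean within-group SD: width 2 = 3.07, width 4 = 0.88
dispersion t-test: t = 21.2, p = 2.97e-62
```

Every promoter carries one site, the 2-nt grouping realises all 4⁴ = 256
flank keys, and — because the generator plants expression means on the
width-4 key — grouping at width 4 cuts the mean within-group standard
deviation from 3.07 to 0.88 bins, a difference the t-test calls decisively.

The same pattern works for the structural side:

```python
from yreflank.helical import compare_bound_unbound
from yreflank.synthetic import HelicalSeriesSpec, gen_helical_series

spec = HelicalSeriesSpec(seed=11, n_frames=2000, displacement=1.0,
                         reach_5p=4, reach_3p=0)
bound, unbound, truth = gen_helical_series(spec)
res = compare_bound_unbound(bound, unbound, "shift")
print(f"altered flank reach: 5' = {res.reach_5p} steps, "
      f"3' = {res.reach_3p} steps")
```

prints `altered flank reach: 5' = 4 steps, 3' = 0 steps` — the planted
asymmetric four-step 5′ alteration is recovered exactly.

A command line wraps the same functionality:

```sh
yreflank synth --out run/synth --seed 3        # generate inputs + truth
yreflank promoters run/synth/promoters.tsv --out run/groups --seed 3
yreflank helical bound_shift.ser unbound_shift.ser --out run/helical
yreflank contacts complex.pdb --out run/contacts
yreflank ensemble complex.pdb --out run/rmsd
```

Each run writes text tables plus a `manifest.json` recording the config,
input hashes and seed.

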