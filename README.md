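# msidissect

Dissecting intratumor heterogeneity in MALDI mass spectrometry imaging
(MALDI-MSI) of combined hepato-cholangiocarcinoma (cHCC-CCA) — a primary
liver tumor that contains both hepatocellular (HCC) and cholangiocarcinoma
(iCCA) components in one lesion. A MALDI-MSI acquisition yields a tryptic-
peptide mass spectrum at every pixel of a tissue section (m/z 600–3200 at a
nominal 100 µm raster); `msidissect` turns those pixel spectra into:

- **spatial segmentation** — hierarchical bisecting k-means over the aligned
  peak table with weak spatial denoising, yielding an arborescence whose
  first split separates the two molecular phenotypes, plus relative
  quantification of each component (spectra per cluster / total spectra per
  case);
- **PCA** of individual pixel spectra with unit-variance scaling, score
  images and loading extremes (the peaks specific to either component);
- **virtual immunohistochemistry** — in silico tryptic digestion of marker
  proteins (cleave after K/R, not before P), selection of proteome-unique
  peptides ([M+H]⁺ in the acquisition window, I/L treated as equivalent),
  matching into the MSI peak list, and ion images whose overlap with
  annotated regions is scored with Dice and IoU;
- a **phantom generator** that emulates the tissue organisation the analysis
  assumes (two phenotype fields, fibrosis sub-domains, hidden foci,
  TIC variation, peak noise), so the whole chain is testable without any
  tissue data.

Intended users: computational proteomics / digital-pathology researchers who
want a transparent, scriptable reimplementation of the standard commercial
MSI segmentation-and-virtual-staining workflow.

## Core methods

Preprocessing per pixel spectrum *s(m/z)*:

1. baseline: grey-scale opening (moving min then max, window 2·h+1 bins)
   smoothed by a moving average of the same width, subtracted and clipped
   at 0;
2. TIC normalization: *s → s · T / Σs* so every pixel carries total ion
   current *T*;
3. peak picking: local maxima ≥ snr · (1.4826 · MAD) of non-zero
   intensities;
4. alignment: pooled peaks split into bins wherever the m/z gap exceeds a
   tolerance (default 0.3 Da); bin center = intensity-weighted mean.

Segmentation: recursive 2-means (k-means++, 10 restarts, seeded) on the
pixels × bins matrix, columns unit-variance scaled; after each split a 3×3
median filter on the binary label image ("weak denoising"). Component
percentages are rounded half-up to one decimal.

Peptide masses: [M+H]⁺ = Σ residue masses + 18.010565 (H₂O) + 1.007276
(proton), monoisotopic or average tables, cysteine unmodified. A peptide is
proteome-unique iff its I/L-collapsed sequence occurs in exactly one
protein record.

Overlap: Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B| between the
Otsu-binarized ion image and the annotated region mask.

## Worked example

```python
import msidissect as md

spec, ctx = md.default_phantom_spec(seed=1)
dataset, annotation, truth = md.make_phantom(spec)
table = md.build_peak_table(dataset)
print(f"peak table: {table.n_pixels} pixels x {table.n_bins} bins "
      f"({int(table.empty_rows().sum())} off-tissue)")

tree = md.segment(table, depth=1, denoise="weak", seed=1)
assigned = md.assign_components(tree, 1, annotation=annotation)
print("component percentages:", md.quantify(assigned["label_map"]).percentages)
print("planted fractions:    ",
      {k: round(v, 1) for k, v in md.phenotype_fractions(annotation).items()})
print("segmentation ARI:      %.3f" % md.segmentation_ari(tree, annotation))

marker = ctx["markers"]["MKC01"]                  # an iCCA-like marker
for pep in md.select_marker_peptides(marker, ctx["proteome"], n=2):
    print(f"unique peptide {pep.sequence[:12]}... [M+H]+ = {pep.mh_mono:.4f} Da")
panel = md.virtual_panel([(marker, "iCCA")], ctx["proteome"], table, annotation)
print(panel[["marker", "target_mz", "region_name", "dice", "iou"]]
      .round(3).to_string(index=False))
```

prints

```
peak table: 3600 pixels x 63 bins (240 off-tissue)
component percentages: {'HCC': 46.9, 'iCCA': 53.1}
planted fractions:     {'iCCA': 53.4, 'HCC': 46.6}
segmentation ARI:      0.978
unique peptide LDEQNFLYESVL... [M+H]+ = 2950.4931 Da
unique peptide HSGFGEPLQDSL... [M+H]+ = 2475.1034 Da
marker  target_mz region_name  dice   iou
 MKC01   2950.494        iCCA 0.894 0.808
 MKC01   2475.104        iCCA 0.894 0.808
```

i.e. the depth-1 segmentation recovers the planted component fractions to
within half a percentage point (adjusted Rand index 0.978 against the
planted phenotypes), and both proteome-unique peptides of the iCCA-like
marker produce ion images overlapping the annotated iCCA region at
Dice ≈ 0.89.

The same stages are available from the shell:

```bash
msidissect phantom --seed 1 --out ph/
msidissect preprocess ph/phantom.imzML --out peak_table.csv
msidissect segment peak_table.csv --annotation ph/annotation.csv ph/legend.csv
msidissect all --config run.yaml     # full chain with provenance
```

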