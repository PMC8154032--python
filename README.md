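# pcps — spliced-peptide prediction and MS assignment

Proteasome-catalyzed peptide splicing (PCPS) lets the 20S proteasome ligate
two of its own cleavage products into a peptide whose sequence does not
occur in the parent protein. Such *splicetopes* are candidate HLA class I
epitopes — attractive immunotherapy targets when a driver mutation (e.g.
KRAS G12V, RAC2 P29L) yields no usable linear neoepitope — but they must be
found by "reverse immunology": enumerate every splice product a substrate
could theoretically yield, then look for those masses in the LC-MS data of
an in-vitro proteasome digest. This package implements that pipeline for
researchers running in-vitro PCPS experiments:

* **Candidate enumeration.** A cleavage product is `P(i, j)`, the contiguous
  fragment from residue *i* to *j* (1-based, inclusive, full-protein
  numbering). A splice product `SP(i, j, k, l)` is `P(i, j)` ligated to
  `P(k, l)`, with length `j + l − i − k + 2`, in *normal* order
  (`j < k`), *inverse* order (`l < i`), or *overlapping* (the fragments
  share positions); trans products combine fragments from two substrate
  molecules. Enumeration is constrained by fragment-length (MinP/MaxP),
  gap (MinG/MaxG) and total-length (MinS/MaxS) bounds, excludes contiguous
  normal products (`j + 1 = k`, identical to the plain cleavage product) and
  optionally any product whose sequence occurs in the substrate.
* **Mass annotation and FASTA output.** Every candidate carries its neutral
  monoisotopic mass and m/z at z = 1, 2, 3 (`(M + z·m_H+)/z`), written as a
  searchable two-line FASTA database.
* **Analytic size prediction.** A length-L substrate has `L(L+1)/2`
  fragments and hence `(L(L+1)/2)²` ordered fragment pairs — 25,502,500 for
  L = 100 — so counts (restricted or not) are computed in closed form
  *before* deciding to enumerate.
* **Tiered MS1 assignment.** Peaks are matched within a ppm tolerance and
  scored on mass accuracy, charge-state co-occurrence, retention-time
  similarity, and b/y fragment coverage. Acceptance is tiered:
  conventional cleavage products first; chemically modified peptides only
  if their unmodified form was identified; splice products only if *both*
  constituent fragments were identified as conventional peptides.
* **Artifact audits.** A t = 0 screen flags splice-product masses already
  present in the undigested substrate, and a deletion-variant audit reports
  whether a candidate could equally derive from a faulty synthesis product
  of the substrate missing a few residues — the key confound for
  hydrophobic substrates.
* **Synthetic spectra.** A seeded generator plants peptide signals with
  charge-state distributions, ppm jitter and uniform noise, with a truth
  table for exact recovery scoring.

## Worked example

```python
from pcps import (EnumerationParams, enumerate_psps, predict_database_size,
                  deletion_artifact_check, get_substrate)

kras = get_substrate("KRAS_G12V_2-14")          # TEYKLVVVGAVGV, offset 2
params = EnumerationParams(min_part=2, max_part=8, min_len=9, max_len=9)

report = predict_database_size(kras.L, params)
print(f"predicted: {report.n_pcps} PCPs, {report.n_psps} PSPs")

for rec in enumerate_psps(kras, params):
    p = rec.product
    if (p.i, p.j, p.k, p.l) in {(5, 8, 10, 14), (5, 9, 11, 14), (5, 10, 12, 14)}:
        print(f"{p.i}-{p.j}/{p.k}-{p.l} {rec.sequence}  M={rec.mass:.5f}  "
              f"z1={rec.mz1:.5f} z2={rec.mz2:.5f}")

amb, wit = deletion_artifact_check("KLVVGAVGV", get_substrate("KRAS_G12V_1-21"), d_max=1)
print(f"deletion-artifact ambiguous: {amb}, witness: delete position {wit[0]}")
```

prints

```
predicted: 63 PCPs, 150 PSPs
5-8/10-14 KLVVGAVGV  M=840.54326  z1=841.55053 z2=421.27890
5-9/11-14 KLVVVAVGV  M=882.59020  z1=883.59748 z2=442.30238
5-10/12-14 KLVVVGVGV  M=868.57456  z1=869.58183 z2=435.29455
deletion-artifact ambiguous: True, witness: delete position 9
```

The three 9mers are the KRAS G12V splice candidates at coordinates
5-8/10-14, 5-9/11-14 and 5-10/12-14; their masses and m/z values are what
an MS search engine would look for. The last line is the cautionary tale:
deleting the single valine at protein position 9 from the synthetic
substrate produces a molecule that *contains* KLVVGAVGV, so a matching MS
peak cannot by itself distinguish true splicing from a synthesis artifact.

The same engine drives the `pcps` command line
(`build-db`, `predict-size`, `filter-affinity`, `assign`,
`screen-baseline`, `check-artifacts`, `kinetics`, `simulate`), e.g.

```
$ pcps predict-size --length 100 --order all --unrestricted
n_pcps = 5,050
n_psps = 25,502,500
n_total = 25,507,550
estimated_bytes = 3,647,579,650
```

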