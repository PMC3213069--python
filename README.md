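# nmrmatch

Metabolite fingerprinting for 1D ¹H-NMR mixtures: identify which known
compounds are present in a complex sample by matching its spectral peaks
against a reference library of single-metabolite peak lists — no
quantification, no deconvolution, just fast, ranked identification.

## Who this is for

Metabolomics practitioners who have a processed 1D ¹H-NMR spectrum (or an
externally picked peak list) of a biofluid, extract or chemical mixture,
and a curated library of reference peak lists (each with acquisition
metadata: provenance, metabolite type, sample pH, solvent, spectrometer
frequency), and want a ranked list of candidate metabolites with
principled scoring and benchmarking machinery.

## The method

All chemical shifts are canonicalized to 0.01 ppm precision. A candidate
metabolite with `matched` of its `total` library peaks found in the query
is ranked by the **significance score**

```
score = matched / (total + 1)
```

Unlike the plain fraction `matched/total` used by earlier search tools,
this score strictly prefers the peak-richer candidate among metabolites
with the same matched fraction: 2 of 4 peaks scores 0.40 while 5 of 10
peaks scores 0.45 and ranks higher. Candidates scoring at least a
confidence threshold *r* (default 0.5) are reported.

Three search strategies share this score:

* **MH1** — exact matching: a library peak matches only a query peak at
  the same canonical coordinate.
* **MH2** — tolerance matching: a library peak *q* matches if a query
  peak lies in the inclusive window [*q* − τ, *q* + τ], compensating for
  pH/instrument-driven peak drift. With τ = 0 it is identical to MH1.
* **MH3** — greedy mutually exclusive assignment: repeatedly emit the
  best-scoring candidate and remove the query peaks it consumed, so later
  candidates cannot reuse them. Fewer false positives, at the cost of
  false negatives for metabolites with heavily overlapping peaks.

The package also ships a synthetic-data module (libraries, pooled
mixtures, peak-removal and shift-perturbation noise, Lorentzian spectrum
rendering) and evaluation machinery (confusion matrices, ROC/AUC with
optimal cut-off selection, recovery and rank metrics), so every benchmark
runs without downloading any database.

## Worked example

```python
from nmrmatch import *

lib = ReferenceLibrary([
    MetaboliteRecord(id="ALA", name="alanine-like", peaks=(Peak(1.47, 80.0), Peak(3.77, 40.0))),
    MetaboliteRecord(id="LAC", name="lactate-like", peaks=(Peak(1.32, 90.0), Peak(4.11, 35.0))),
    MetaboliteRecord(id="GLC", name="glucose-like",
                     peaks=tuple(Peak(p, 30.0) for p in (3.24, 3.40, 3.46, 3.53, 3.72, 3.89, 4.64, 5.23))),
])
sample = PeakList.from_pairs([(1.32, 88.0), (4.11, 30.0), (3.24, 28.0), (3.40, 25.0),
                              (3.46, 22.0), (3.72, 20.0), (5.23, 18.0), (8.45, 5.0)])
results = search(sample, lib, SearchConfig(method="MH1", r=0.5))
print(results_to_frame(results, lib).to_string(index=False))
```

prints

```
 rank  id         name score  score_full  matched  total source     mtype  ph solvent  frequency
    1 LAC lactate-like  0.67    0.666667        2      2   user mammalian 7.0   water      500.0
    2 GLC glucose-like  0.56    0.555556        5      8   user mammalian 7.0   water      500.0
```

Both lactate-like peaks are found in the sample (score 2/(2+1) = 0.67,
rank 1); five of the eight glucose-like peaks are found (5/(8+1) = 0.56,
rank 2); alanine-like matches nothing and the residual peak at 8.45 ppm
belongs to no candidate. Raising `r` above 0.67, or switching to
`method="MH3"` after a competitor consumes the shared coordinates, prunes
the list further.

The same search is available from the shell:

```sh
nmrmatch simulate --k 100 --n 10 --seed 7 --outdir sim
nmrmatch search sim/mixture_peaks.tsv --library sim/library.tsv \
    --method MH2 --shift-tolerance 0.01 --confidence-threshold 0.5 --out results.tsv
nmrmatch evaluate --experiment recovery --library sim/library.tsv --out recovery.tsv
```

Every command writes a `*.manifest.json` with the resolved parameters and
seeds, sufficient to replay the run.

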