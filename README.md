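# connectax

Cross-species brain-network comparison pipeline. Given a set of equally
parcellated, weighted, undirected connectomes with taxonomic labels, it

- computes normalized-Laplacian eigenspectra (optionally Gaussian-smoothed,
  σ=0.015 on a 2000-point grid) and **spectral distances** (1 − cosine
  similarity of eigenvalue vectors);
- computes 22-entry multiscale **topological feature vectors** (mean/SD of
  binary and weighted degree/strength, clustering, betweenness, closeness,
  plus characteristic path length, transitivity and assortativity) with the 9
  local/global × binary/weighted subsets, and the corresponding cosine
  distances;
- averages distance matrices over replica resampling (one random scan per
  species per iteration);
- compares intra- vs inter-order distances with Welch's *t* + Cohen's *d* and
  Mann–Whitney *U* + common-language effect size, with order-block medians,
  density residualization (linear/exponential fits, R² > 0.1), MDS embedding
  and hierarchical clustering;
- characterizes global organization: small-worldness against 1000
  degree-preserving rewired nulls, consensus Louvain communities, rich-club
  detection with permutation tests, and four-way edge classification
  (modular / hemispheric / length terciles / rich-club–feeder–peripheral)
  with per-order proportion summaries;
- ships a **synthetic taxonomy generator** (per-order stochastic-block-model
  archetypes, bilateral geometry, distance-dependent log-normal weights,
  degree-preserving species perturbations, replica noise) so the entire
  pipeline is testable without any external data.

## Command-line interface

```bash
# generate a synthetic taxonomy (YAML spec optional; defaults: 6 orders x 5
# species, 200 nodes)
connectax --out-dir demo generate

# feature / spectra tables
connectax --out-dir demo features --dataset demo/manifest.tsv --subset all
connectax --out-dir demo spectra  --dataset demo/manifest.tsv

# replica-resampled distance matrix + intra/inter comparison
connectax --out-dir demo distances --dataset demo/manifest.tsv \
    --metric spectral --n-iter 1000 --no-filter
connectax --out-dir demo compare --dm demo/distances.tsv \
    --species demo/manifest.tsv

# organization statistics and edge-class proportions
connectax --out-dir demo orgstats --dataset demo/manifest.tsv --n-null 100
connectax --out-dir demo classify-edges --dataset demo/manifest.tsv --n-null 100

# end-to-end JSON summary (both metrics)
connectax --out-dir demo report --dataset demo/manifest.tsv --n-iter 1000
```

Global flags: `--config config.yaml`, `--seed`, `--log-level`, `--out-dir`.
Config keys and defaults are in `connectax/config.py`.

## Data layout

- connectivity matrix: CSV, N×N numeric, no header;
- node metadata: TSV `node_id  hemisphere(L/R)  x  y  z`;
- manifest: TSV `species_id  order  superorder  sample_id  matrix_path
  metadata_path` (paths relative to the manifest).

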