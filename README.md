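# geoassign

Geographic-origin inference for wildlife samples from microsatellite
(STRP) genotype profiles. The package fits Bayesian spatially smoothed
allele-frequency surfaces over georeferenced reference sites and assigns
unknown-origin samples either to one of the sampled sites (smoothed
assignment, **SAM**) or to continuous coordinates inside a habitat
boundary polygon (continuous assignment, **CAM**). mtDNA haplogroups,
derived from a median-joining haplotype network, can be encoded as an
extra haploid pseudo-locus. A validation suite provides leave-one-out
cross-validation, confusion matrices, distance quantiles, zone
containment, haplogroup concordance, and a negative-control draw-fraction
t-test.

## Layout

| module | contents |
| --- | --- |
| `geoassign.io_formats` | two-line-per-individual genotype dialect, site files, ≥6-locus suitability filter, haplogroup pseudo-locus encoding |
| `geoassign.haplotypes` | alignment handling, median-joining network, hypermutable-site masking, nearest-reference haplogroup labelling |
| `geoassign.spatial` | haversine distances, exponential-decay covariance, softmax frequency transform, genotype likelihoods, Metropolis-within-Gibbs surface fitting, kriging |
| `geoassign.assignment` | boundary polygons, SAM multi-run consensus, CAM coordinate MCMC, median point estimates, weighted confidence draws |
| `geoassign.validation` | LOOCV, confusion/accuracy summaries, distance quantiles, zone containment, concordance, Welch t-test |
| `geoassign.synthetic` | seeded synthetic landscapes (spatially autocorrelated frequencies, river-barrier shift with contact-zone taper, barrier-linked haplogroups, missingness), unknown-origin queries, plain-text fixture bundles |
| `geoassign.datasets` | bundled published reference data: site codes/zones, the two study boundary polygons, the reference cross-validation confusion matrix, the per-animal query summary |
| `geoassign.cli` | `geoassign` command-line pipeline |

## CLI

```sh
geoassign simulate --seed 1 --out fixture/            # synthetic bundle
geoassign fit --genotypes g.txt --sites sites.txt --out fit/
geoassign sam --genotypes g.txt --sites sites.txt --queries q.txt --out sam/
geoassign cam --genotypes g.txt --sites sites.txt --queries q.txt \
    --boundary boundary.txt --out cam/
geoassign haplonet --fasta hvr1.fasta --references refs.fasta --out net/
geoassign validate --genotypes g.txt --sites sites.txt --out val/
geoassign reproduce-synthetic --seed 1 --out repro/   # end-to-end smoke
```

MCMC settings default to the full-scale schedule (thinning 500, burn-in
1000, 2000 retained iterations, 5 runs) and can be overridden with a YAML
`--config` (`thinning`, `burn_in`, `iterations`, `runs`). Every output
directory gets a `manifest.json` with the seed, the echoed configuration
and SHA-256 hashes of all outputs; identical seed + config reproduce
byte-identical outputs.

File dialects: genotypes are whitespace-delimited, two lines per
individual (`id site_index allele…`), `-999` missing, site index `-1` for
unknown origin; haploid pseudo-loci put their allele on the first line and
`-999` on the second. Site files are `code index lat lon zone` with zone
in `{North, Transition, South}`. Boundary polygons are `lat lon` vertex
lines.

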