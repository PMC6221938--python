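# liquidbiopsy

A toolkit for tracking tumor-derived DNA in blood plasma, built around three
computational stages and a synthetic-data module that makes every stage
verifiable without external data:

1. **Variant selection** (`liquidbiopsy.variants`) — reduce a patient's
   annotated somatic SNV list to a single plasma-trackable ddPCR target:
   keep rare (population AF < 0.01) non-synonymous SNVs, drop tumor
   VAF < 20%, then prioritize by tier (disease-associated gene > cancer
   census gene > high CADD/SIFT pathogenicity), with a full audit trail.
2. **ddPCR quantification** (`liquidbiopsy.ddpcr`) — classify two-channel
   droplet amplitudes (or consume class counts), apply the Poisson occupancy
   correction `λ = −ln(1 − p)`, and report concentrations, lambda-corrected
   VAF, copies and positive droplets per mL plasma, a positivity call
   (default: ≥ 2 mutant-containing droplets) and a per-sample detection
   limit (threshold / informative droplets).
3. **CNV profiling** (`liquidbiopsy.cnv`) — tile the genome into fixed
   50 kb bins, count read starts per bin, form library-normalized,
   median-centered tumor/normal log2 ratios with low-coverage masking, and
   compare profiles (Pearson r), score instability (fraction of genome
   altered) and estimate amplitude attenuation between profiles.

`liquidbiopsy.synthetic` generates every input with known ground truth
(Poisson droplet loading, segmental copy-number truths with purity,
overdispersed binned counts, variant tables with known survivor sets), and
`liquidbiopsy.pipeline` orchestrates a per-patient case into a versioned,
deterministic JSON report.

## CLI

```bash
# synthetic inputs with ground-truth sidecars
liquidbiopsy simulate cnv --seed 1 --out-dir sim/cnv --n-events 8
liquidbiopsy simulate droplets --seed 1 --out-dir sim/dd --lambda-mut 0.01
liquidbiopsy simulate variants --seed 1 --out-dir sim/var

# stage commands
liquidbiopsy select-variant --variants sim/var/variants.tsv
liquidbiopsy ddpcr --counts sim/dd/droplet_counts.tsv --threshold 2
liquidbiopsy cnv logr --genome sim/cnv/chrom.sizes \
    --tumor sim/cnv/tumor_counts.tsv --normal sim/cnv/normal_counts.tsv \
    --out profile.tsv
liquidbiopsy cnv compare --genome sim/cnv/chrom.sizes \
    --normal sim/cnv/normal_counts.tsv \
    --sample-a sim/cnv/tumor_counts.tsv --sample-b profile_b_counts.tsv

# full per-patient workflow from a case YAML
liquidbiopsy run --case case.yaml --out report.json
```

A case YAML points at a variant TSV, a `chrom.sizes` genome table, per-bin
count TSVs (normal / tumor / plasma timepoints) and per-well droplet count
TSVs per timepoint; see `liquidbiopsy.pipeline.PatientCase.from_yaml` for
the schema. Sections whose inputs are absent appear in the report as
explicit `not_computed` entries.

## File formats

Plain text throughout: BED (0-based half-open) for read positions,
headered TSVs for counts, droplet classes, amplitudes and variant tables,
two-column `chrom.sizes` for genomes, canonical JSON for reports and
ground-truth sidecars. VCF input is supported with a TSV annotation sidecar
keyed `chrom:pos:ref:alt`.
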