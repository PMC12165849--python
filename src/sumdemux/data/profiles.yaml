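# Named per-experiment QC filter presets.  Each threshold carries its value
# and whether the comparison is inclusive (>= / <=) or strict (> / <).
# Any field may be overridden at run time; unset thresholds are inert.

species_mix:
  atac:
    min_fragments: {value: 1000, inclusive: true}
    min_tss: {value: 5, inclusive: true}
  rna: {}

macrophage:
  atac:
    min_fragments: {value: 3000, inclusive: false}
    min_tss: {value: 3, inclusive: true}
    min_promoter_ratio: {value: 0.08, inclusive: true}
    max_nuclei_per_droplet: {value: 5, inclusive: true}
  rna:
    min_genes: {value: 150, inclusive: false}
    max_nuclei_per_droplet: {value: 6, inclusive: false}

tcell:
  atac:
    min_fragments: {value: 1000, inclusive: true}
    min_tss: {value: 5, inclusive: true}
    min_fip_fraction: {value: 0.35, inclusive: true}
    min_promoter_ratio: {value: 0.07, inclusive: true}
  rna:
    min_genes: {value: 400, inclusive: false}
    umi_range:
      min: {value: 600, inclusive: false}
      max: {value: 5000, inclusive: false}
    max_pct_mito: {value: 10, inclusive: false}

crispr:
  atac:
    min_fragments: {value: 1000, inclusive: true}
    min_tss: {value: 5, inclusive: true}
    min_promoter_ratio: {value: 0.07, inclusive: true}
    min_fip_fraction: {value: 0.2, inclusive: true}
  rna:
    min_umis: {value: 200, inclusive: false}
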