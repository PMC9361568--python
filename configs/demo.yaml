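# End-to-end demo on synthetic data: simulate an admixed cohort with truth
# tracts/IBD and a sibling map pair, score corrupted tracts, assign IBD
# ancestries, compare the maps, and run the dual-map iHS scan.
stages:
  - stage: simulate
    params:
      chrom_length_bp: 8000000
      background_rate: 1.0e-8
      hotspot_rate: 1.5
      intensity_fold: 60.0
      shared_fraction: 0.8
      n_sites: 800
      n_individuals: 30
      n_generations: 14
      switch_error_per_mb: 0.3
      min_cm: 1.0
  - stage: lai_accuracy
    params:
      truth: truth_tracts.tsv
      inferred: inferred_tracts.tsv
  - stage: ibd_assign
    params:
      ibd: true_ibd.tsv
      tracts: truth_tracts.tsv
      map: map.hapmap.txt
      min_cm: 1.0
  - stage: map_compare
    params:
      maps: [map.hapmap.txt, map_sibling.hapmap.txt]
      min_overlap: 50
      call_hotspots: true
  - stage: ihs_scan
    params:
      haplotypes: cohort.haps.tsv
      maps: [map.hapmap.txt, map_sibling.hapmap.txt]
      genes: genes.txt
      fraction: 0.05
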