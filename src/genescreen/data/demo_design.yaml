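# Demo synthetic-community design: one species is a self-sufficient PHB
# producer (Case I), the ectoine gene set is split across two taxa so only
# the pooled community completes it (Case II), and no taxon carries the
# lutein-specific genes (Case III).
seed: 42
unclassified_fraction: 0.1
count_model: {family: log-uniform, low: 50, high: 15000}
background_per_weight: 100
contigs_per_taxon: 4
taxa:
  - name: Methyloceanibacter caenitepidi
    lineage: [Bacteria, Proteobacteria, Alphaproteobacteria, Hyphomicrobiales,
              Methyloligellaceae, Methyloceanibacter, Methyloceanibacter caenitepidi]
    weight: 2.0
    products:
      PHB: complete
      ectoine: {missing: [ectA, ectC]}
  - name: Halomonas-like sp.
    lineage: [Bacteria, Proteobacteria, Gammaproteobacteria, Oceanospirillales,
              Halomonadaceae, Halomonas, Halomonas-like sp.]
    weight: 1.0
    products:
      ectoine: {missing: [lysC, asd]}
  - name: Caldilinea aerophila
    lineage: [Bacteria, Chloroflexi, Caldilineae, Caldilineales,
              Caldilineaceae, Caldilinea, Caldilinea aerophila]
    weight: 1.5
    products:
      acetoin: complete
      2,3-butanediol: complete
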