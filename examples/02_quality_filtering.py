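"""Post-denoising quality control: screening, abundance filter, rarefaction.

Screens a few representative sequences, removes OTUs seen fewer than 25
times across the whole data set, drops a chloroplast OTU via the
taxonomy blacklist, and rarefies every sample to 2,500 reads.
"""

import bogwater as bw

# -- sequence screening ------------------------------------------------
seqs = [
    ("clean", "ACGT" * 37 + "AC"),            # 150 bp, well-behaved
    ("has_N", "ACGT" * 37 + "AN"),            # ambiguous base call
    ("homopolymer", ("A" * 9 + "CGT" * 47)[:150]),  # 9-base run
    ("too_short", "ACGTACGT"),
]
kept, removed = bw.screen_sequences(seqs, max_homopolymer=8,
                                    length_range=(148, 152))
print(f"screening kept {[n for n, _ in kept]}, "
      f"removed {[n for n, _ in removed]}")

# -- whole-data-set abundance filter and rarefaction -------------------
cfg = bw.small_config(seed=2)
table, metadata, tree, truth = bw.simulate_timeseries(cfg)
filtered = bw.filter_rare_otus(table, min_total=25)
print(f"abundance filter: {table.n_otus} -> {filtered.n_otus} OTUs "
      f"(dropped OTUs with < 25 reads data-set-wide)")

rarefied, report = bw.rarefy(filtered, depth=2500, seed=2)
print(f"rarefaction to {report.rarefaction_depth}: kept "
      f"{rarefied.n_samples} samples, dropped {report.n_samples_dropped}")
print(f"every retained sample now has exactly "
      f"{rarefied.sample_totals().max()} reads")

# -- taxonomy blacklist (e.g. chloroplast removal) ----------------------
t = bw.OtuTable([[10, 20]], ["s1"], ["chloro", "bacterial"])
assigns = [
    bw.TaxonomyAssignment(
        "chloro", (("kingdom", "Bacteria"), ("phylum", "Cyanobacteria"),
                   ("class", "Chloroplast")), (100.0,) * 3, "comprehensive"),
    bw.TaxonomyAssignment(
        "bacterial", (("kingdom", "Bacteria"), ("phylum", "Actinobacteria"),
                      ("class", "Actinomycetia")), (100.0,) * 3,
        "comprehensive"),
]
clean = bw.remove_blacklisted_taxa(t, assigns, {"Chloroplast"})
print(f"blacklist removal kept: {clean.otu_ids}")
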