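"""Call transcription-factor binding events on a simulated promoter array.

Builds a 200-promoter tiling layout, plants fold-3 binding events in 10%
of promoters, simulates three replicate two-colour arrays with log-normal
probe noise, and runs the peak caller with the standard filters
(p < 0.01 in >= 2 of 3 replicates, consensus height > 1.5).
"""

from promchip import FragmentLengthDist, chip, peak_shape, synthetic

shape = peak_shape(FragmentLengthDist.uniform())  # 200-700 bp sonication range

layout = synthetic.generate_layout(n_genes=200, seed=11)
truth = synthetic.make_chip_truth(layout, bound_fraction=0.10, fold=3.0,
                                  condition="stimulated", seed=12)
arrays = synthetic.simulate_chip_arrays(layout, truth, noise_sd_log2=0.1,
                                        n_replicates=3, seed=13, shape=shape)

calls = chip.call_condition(arrays, shape, "stimulated", n_perm=199, seed=14)

planted = set(truth.loc[truth["true_fold"] > 1, "gene_id"])
called = {c.gene_id for c in calls if c.passes}
tp = called & planted

print(f"planted events : {len(planted)}")
print(f"called bound   : {len(called)}")
print(f"true positives : {len(tp)}  (sensitivity {len(tp) / len(planted):.2f})")
for c in calls:
    if c.passes:
        t = truth.set_index("gene_id").loc[c.gene_id]
        print(f"  {c.gene_id}: centre {c.consensus_center:+7.0f} bp "
              f"(true {t['true_center']:+5d}), height {c.consensus_height:.2f} "
              f"(true {t['true_fold']:.1f})")
        if len(tp) and c.gene_id == sorted(tp)[2]:
            break

# The centre is the fitted binding-site position relative to the TSS and
# the height its fold enrichment over the background IP/mock ratio; with
# fold-3 events and 0.1 log2 noise the caller recovers essentially every
# planted promoter with no false calls.
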