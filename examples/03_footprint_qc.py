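"""Ribosome-footprint quality control: periodicity and stop-codon drop-off.

Generates footprints with a 90% in-frame fraction and 2% stop-codon
read-through, infers P-sites with the +12 offset and prints the two QC
statistics a clean library should show.
"""

import riboshift as rs

cds = rs.make_cds_model(n_genes=25, seed=3)
footprints = rs.generate_footprints(60000, in_frame_fraction=0.9,
                                    cds_model=cds, seed=4,
                                    readthrough_fraction=0.02)
psites = rs.infer_psites(footprints, cds, offset=12)

per = rs.periodicity(psites)
profile, ratio = rs.stop_dropoff_profile(psites, cds, window=30)

print(f"{len(psites)} P-sites inferred (+12 nt from the 5' end, strand-aware)")
print(f"3-nt periodicity: {100 * per:.1f}% of CDS-internal P-sites in frame 0")
print("  (a fully random library gives 33%; real libraries exceed ~86%)")
print(f"stop-codon drop-off ratio: {ratio:.3f}")
print("  (post-stop over pre-stop P-site density; ~0 means ribosomes "
      "terminate cleanly — here 2% read-through was planted)")
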