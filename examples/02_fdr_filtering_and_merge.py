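"""Target-decoy FDR filtering and cross-engine merging.

Simulates a two-Gaussian PSM score distribution (true targets vs
null/decoys), estimates q-values, filters at 1% FDR, and shows that the
observed false-discovery proportion matches the estimate.  Then merges two
engines that disagree on one spectrum.
"""

import gsspipe as g

psms, false_ids = g.simulate_score_calibration(seed=7, n_true=4000, n_false=3000, n_decoy=3000)
kept = g.filter_qvalue(g.estimate_qvalues(psms), threshold=0.01)
fdp = sum(1 for p in kept if p.spectrum_id in false_ids) / len(kept)

print(f"simulated PSMs: {len(psms)} (4000 true targets, 3000 false targets, 3000 decoys)")
print(f"accepted at q<=0.01: {len(kept)}")
print(f"observed false-discovery proportion: {fdp:.4f}  (the estimator promises <= 0.01)")

a = [g.PSM("spec1", "PEPTLDEK", "msgf", 9.0, False, q_value=0.001),
     g.PSM("spec2", "AAAGGGK", "msgf", 8.0, False, q_value=0.002)]
b = [g.PSM("spec1", "PEPTIDEK", "xtandem", 7.5, False, q_value=0.001),
     g.PSM("spec2", "CCCGGGK", "xtandem", 8.1, False, q_value=0.002)]
merged = g.merge_engines([a, b])
print()
print(f"engine merge: kept {len(merged)} peptide(s): {[p.peptide for p in merged]}")
print("spec1 survives (PEPTLDEK == PEPTIDEK after I/L collapse, which MS cannot")
print("distinguish); spec2 is discarded because the engines named different peptides.")
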