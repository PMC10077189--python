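"""Build the translated search databases for a small synthetic genome.

Generates a 150 kb annotated genome, six-frame-translates it into
stop-to-stop ORFs, three-frame-translates its transcripts, digests one
predicted protein tryptically, and assembles the combined target+decoy
search database.
"""

import gsspipe as g

truth = g.generate_genome(seed=1, n_chromosomes=1, n_genes=10, genome_length=150_000)
ev = g.simulate_evidence(truth, seed=2)

genome_orfs = [orf for seq in truth.genome for orf in g.six_frame_translate(seq, min_orf_aa=10)]
transcript_orfs = g.three_frame_translate(ev.transcripts, min_nt=50, min_orf_aa=10)
db = g.build_search_database(truth.annotation, genome_orfs, transcript_orfs)

protein = truth.coding_genes[0].protein
peptides = g.digest_tryptic(protein, max_missed=2, len_range=(7, 45))

print(f"genome ORFs (6-frame, >=10 aa): {len(genome_orfs)}")
print(f"transcript ORFs (3-frame):      {len(transcript_orfs)}")
print(f"search database entries:        {len(db)} ({len(db.targets)} targets + {len(db.decoys)} reversed decoys)")
print(f"tryptic peptides of one {len(protein)}-aa protein (<=2 missed cleavages): {len(peptides)}")
print()
print("The ORF counts are the size of the novelty search space; the 1:1")
print("decoys are what makes target-decoy FDR estimation possible downstream.")
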