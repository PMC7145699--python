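"""Scan a synthetic genome's promoters for AACNDN and tally methylation.

Generates a 100 kb genome with planted motifs and a methylome, runs the
scan -> attach -> census pipeline, and cross-checks the result against the
naive enumeration oracle.
"""

from mybdna import MotifPattern, attach_methylation, scan_motifs, tally_census
from mybdna.synthetic import gen_genome, gen_methylome, oracle_census

bundle = gen_genome(n_chrom=1, chrom_len=100_000, n_genes=30,
                    n_planted_motifs=150, seed=7)
calls_5mc, calls_6ma, truth = gen_methylome(bundle.genome, bundle.truth, seed=8)
calls = list(calls_5mc) + list(calls_6ma)

instances = scan_motifs(bundle.genome, MotifPattern("AACNDN"), bundle.promoters)
census = tally_census(attach_methylation(instances, calls), bundle.promoters)

print(f"promoter windows:        {len(bundle.promoters)}")
print(f"motif instances:         {census['total']}  "
      f"({len(truth['planted'])} planted, rest background matches)")
print(f"genes with >=1 instance: {census['genes_with_instance']}")
print(f"methylated instances:    {census['any_methylated']} "
      f"(5mC@3: {census['5mC_pos3']}, 6mA@1: {census['6mA_pos1']}, "
      f"6mA@2: {census['6mA_pos2']})")
print(f"matches naive oracle:    "
      f"{census == oracle_census(bundle.genome, 'AACNDN', bundle.promoters, calls)}")
# The census counts every promoter occurrence of the degenerate element and
# how often its informative positions (A1, A2, C3) carry 6mA/5mC marks.
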