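"""Localize a linear epitope from peptide alignments.

Aligns a family of 7-mer peptides (windows of the epitope NFTLPSWA, some
mutated) against a 120-aa protein carrying that epitope at positions
51-58, clusters the hits into sites, and prints the major epitope site and
the peak of the per-position score profile.
"""

import numpy as np

from antigenscreen import (
    ProteinRecord,
    ScoringScheme,
    best_local_hit,
    cluster_sites,
    major_epitope_score,
    position_profile,
)

protein = ProteinRecord("ANTIGEN_1", "demo antigen",
                        "M" * 50 + "NFTLPSWA" + "G" * 62)
peptides = ["NFTLPSW", "FTLPSWA", "NFTLPSA", "AFTLPSW", "NFSLPSW"]
scheme = ScoringScheme()

hits = [h for h in (best_local_hit(p, protein, scheme) for p in peptides) if h]
for h in hits:
    print(f"{h.peptide}  protein {h.prot_start}-{h.prot_end}  "
          f"raw {h.raw_score}  bits {h.bit_score:.1f}  E {h.evalue:.2g}")

sites = cluster_sites(hits)
top = sites[0]
print(f"\nmajor epitope site: [{top.site_start}, {top.site_end}] "
      f"({top.n_peptides} peptides, cumulative score "
      f"{major_epitope_score(sites):.1f} bits)")

profile = position_profile(hits, protein.length)
peak = int(np.argmax(profile.values)) + 1
print(f"profile peak at residue {peak} "
      f"(density {profile.values[peak - 1]:.2f} bits/residue); "
      f"total mass {profile.total_mass:.1f} = summed hit bits")
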