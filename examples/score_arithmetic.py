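"""The ranking arithmetic on report-style inputs.

A candidate antigen's initial score is its number of distinct matching
peptides divided by protein length (stringent step 1); its final score is
the sum of all peptide match bit scores divided by protein length
(exhaustive step 2). Both normalize away the fact that chance matches
accumulate in proportion to length.
"""

from antigenscreen import CandidateAntigen, format_final_score, format_initial_score

rows = [
    ("417-aa candidate, summed scores 917.3", 417, None, 917.3),
    ("386-aa candidate, 7 matches, summed scores 2245.2", 386, 7, 2245.2),
    ("69-aa candidate, summed scores 1260.4", 69, 5, 1260.4),
]

for label, length, matches, total in rows:
    c = CandidateAntigen("X", "", length,
                         initial_matches=matches or 0, sum_overall_scores=total)
    init = format_initial_score(c.initial_score) if matches else "-"
    print(f"{label}")
    print(f"  initial score {init}   final score {format_final_score(c.final_score)}")

print("\nNote the 69-aa candidate: a short protein needs far fewer matched"
      "\nscores to reach a high final score — short-protein chance hits are"
      "\nwhy the major-epitope score matters as a secondary criterion.")
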