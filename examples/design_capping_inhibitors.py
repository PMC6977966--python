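"""Rank the four characterized capping inhibitors on an ideal NACore zipper.

Builds the 9-residue parallel in-register homo-zipper fixture, threads each
candidate onto both fibril tips, scores the interfaces and prints the
ranking. Lower composite energy = better predicted binding; the
``mating_disruption`` column is the designed steric clash with the next
incoming strand of the opposing sheet (the growth-blocking mechanism), and
``binds_top``/``binds_bottom`` reproduce the single- vs dual-tip verdict.
"""

from zippercap import (
    ZipperSpec,
    build_ideal_zipper,
    rank_designs,
    reconstruct_paper_candidates,
)

fibril = build_ideal_zipper(
    ZipperSpec(sequence="AVVTGVTAV", n_strands_per_sheet=4)
)
candidates = reconstruct_paper_candidates()

report = rank_designs(
    candidates, fibril, context_layers=2, n_sasa_points=120, sc_density=4.0
)
columns = [
    "label", "sequence", "best_face", "energy", "binds_top",
    "binds_bottom", "hbonds", "mating_disruption",
    "self_aggregation_prone",
]
print(report[columns].to_string(index=False))
print(
    "\nEnergies are in the package's own arbitrary units (lower = better "
    "binding); rankings and verdicts, not absolute values, are the result."
)
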