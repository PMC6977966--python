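"""Cell-seeding readout bookkeeping: puncta normalization and dilutions.

Normalizes intracellular puncta counts by well confluence and summarizes
per condition, then reproduces the transfection dilution arithmetic that
takes a 50 µM aggregation reaction to the 125 nM final monomer
concentration delivered to cells.
"""

from zippercap import PunctaRecord, dilution_chain, normalize_puncta

records = [
    PunctaRecord(210, 0.70, "A1", "seeds alone"),
    PunctaRecord(190, 0.65, "A2", "seeds alone"),
    PunctaRecord(205, 0.72, "A3", "seeds alone"),
    PunctaRecord(12, 0.80, "B1", "seeds + inhibitor"),
    PunctaRecord(8, 0.78, "B2", "seeds + inhibitor"),
    PunctaRecord(15, 0.81, "B3", "seeds + inhibitor"),
    PunctaRecord(0, 0.85, "C1", "inhibitor alone"),
    PunctaRecord(0, 0.83, "C2", "inhibitor alone"),
    PunctaRecord(0, 0.86, "C3", "inhibitor alone"),
]
print(normalize_puncta(records).to_string(index=False))

final_uM = dilution_chain(
    50.0,  # µM monomer in the aggregation reaction
    [
        ("ratio", 20),  # 1:20 into culture medium
        ("ratio", 2),  # 1:1 mix with transfection reagent
        ("volume", 10, 100),  # 10 µL into a 100 µL well
    ],
)
print(f"\nfinal transfected monomer concentration: {final_uM * 1000:.0f} nM")
print("(puncta are reported per well, normalized by confluence; inhibitor-"
      "only wells show none)")
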