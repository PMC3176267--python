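"""Encode protein sequences as mean physicochemical property vectors.

Builds two tiny property tables (hydrophobicity-like and charge-like toy
values) and encodes three short peptides.  Each printed number is the mean
of the property over the peptide's residues — the composition statistic
the whole pipeline runs on.
"""

from physprot import SequenceRecord, encode_dataset
from physprot.io_formats import AAINDEX_ORDER, PropertyTable

hydro = PropertyTable(
    accession="TOYHYD01",
    values={aa: v for aa, v in zip(AAINDEX_ORDER, [
        1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
        3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2])},
    title="toy hydropathy",
)
charge = PropertyTable(
    accession="TOYCHG01",
    values={aa: (1.0 if aa in "RK" else -1.0 if aa in "DE" else 0.0)
            for aa in AAINDEX_ORDER},
    title="toy net charge",
)

records = [
    SequenceRecord(id="hydrophobic", residues="ILVVILAVLI"),
    SequenceRecord(id="acidic", residues="DEEDDEEDGS"),
    SequenceRecord(id="basic", residues="KRKKRRKGST"),
]

matrix = encode_dataset(records, [hydro, charge])
print("sequence      ", "  ".join(f"{f:>9}" for f in matrix.feature_ids))
for sid, row in zip(matrix.sample_ids, matrix.X):
    print(f"{sid:<14}", "  ".join(f"{v:9.3f}" for v in row))
print()
print("Hydrophobic peptides score high on the hydropathy mean; acidic and")
print("basic peptides split on the charge mean. These per-property means")
print("are the features the classifier sees.")
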