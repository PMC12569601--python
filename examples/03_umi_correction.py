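"""Directional UMI correction vs the faulty one-pass scheme.

A single mRNA molecule tagged AAAA was sequenced deeply; PCR and
sequencing errors produced satellite UMIs AAAT (one error) and AATT
(two errors).  Directional clustering follows the error chain and
recovers one molecule.  A one-pass corrector reassigns every UMI
simultaneously to its best higher-read neighbor, so AATT is "corrected"
onto AAAT — a UMI that is itself an error — and two molecules are
reported.
"""

from gtnorm import UmiRecord, count_matrix_from_records, directional_clusters, onepass_correction

group = [("AAAA", 10), ("AAAT", 2), ("AATT", 1)]
print("reads per UMI:", dict(group))

res = directional_clusters(group)
print(f"directional: {res.corrected_umi_count} cluster(s), "
      f"members {res.clusters}, representative {res.representatives}")

corrected = onepass_correction(group)
print(f"one-pass   : {corrected} -> {len(set(corrected.values()))} distinct UMIs")

records = [UmiRecord("CELL1", "GENE1", umi, reads) for umi, reads in group]
for method in ("directional", "onepass", "none"):
    mat = count_matrix_from_records(records, method=method)
    print(f"count with method={method!r}: {mat.matrix.toarray()[0, 0]}")
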