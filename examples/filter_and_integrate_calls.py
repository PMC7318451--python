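"""Filter CNV calls with breakpoint/coverage evidence and build a core set.

Calls from two simulated accessions are filtered under the read-depth
profile (breakpoint support >= 5 for deletions, coverage conditions for
duplications), merged within each accession, and integrated across
accessions into a core CNV table with presence columns.
"""

import copyvar as cv

calls_by_accession = {}
for accession, seed in (("acc1", 11), ("acc2", 12)):
    events = (
        cv.CNVEvent("DEL", 5000, 0, tandem=True),
        cv.CNVEvent("DUP", 6000, 3, tandem=False),
    )
    config = cv.SimConfig(genome_length=200_000, cnv_events=events,
                          mean_depth=50.0, seed=seed)
    _, _, truth = cv.simulate_genome_with_cnvs(config)
    tracks, evidence_table = cv.simulate_depth_track(truth, config)
    raw = cv.call_cnvs(tracks["chr1"])
    records = [
        cv.evidence_from_track(c, tracks["chr1"], evidence_table=evidence_table)
        for c in raw
    ]
    kept = cv.filter_calls(raw, records, profile="rd")
    print(f"{accession}: {len(kept)}/{len(raw)} calls pass the rd profile")
    calls_by_accession[accession] = kept

per_accession, core = cv.merge_and_integrate(calls_by_accession)
print("\ncore CNV set (union intervals with per-accession presence):")
print(core.to_string(index=False))
# Each row is one population-level CNV; the accession columns show which
# samples carry it (both implants differ in position between accessions, so
# each appears in exactly one presence column).
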