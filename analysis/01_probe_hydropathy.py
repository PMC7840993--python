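#!/usr/bin/env python
"""Probe-design screen: hydropathy of the p65/RelA transcription factor.

Dye-based thermal-shift probes need a compact hydrophobic core; long
low-hydropathy stretches are candidate disorder-prone regions that
produce high background fluorescence.  This driver profiles the bundled
551-aa p65/RelA sequence (a reconstructed stand-in; see its FASTA
header), reports GRAVY, and locates the low-hydropathy boundary region
that motivates truncating the probe to the aa 1-306 Rel homology
domain.

Writes results/probe_hydropathy.tsv and results/probe_segments.tsv.
"""

from pathlib import Path

from thermoshift.analysis_helpers import load_p65_sequence
from thermoshift.hydropathy import gravy, hydropathy_profile, low_hydropathy_segments
from thermoshift.plate_io import write_results

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    seq = load_p65_sequence()
    profile = hydropathy_profile(seq, window=9)
    segments = low_hydropathy_segments(profile, threshold=-1.5, min_length=10)

    print(f"{seq.id}: {len(seq)} residues")
    print(f"GRAVY = {profile.gravy:.3f} (moderately hydrophilic)")
    g_rhd = gravy(type(seq)(id="p65_1-306", residues=seq.residues[:306]))
    print(f"GRAVY of the aa 1-306 probe region = {g_rhd:.3f}")
    for start, end, mean_score in segments:
        where = "inside aa 1-306" if end <= 306 else "C-terminal to the probe"
        print(f"low-hydropathy segment {start}-{end} (mean {mean_score:.2f}), {where}")

    write_results(
        ({"position": int(p), "score": float(s)}
         for p, s in zip(profile.positions, profile.scores)),
        RESULTS / "probe_hydropathy.tsv",
    )
    write_results(
        ({"start": s, "end": e, "mean_score": m} for s, e, m in segments),
        RESULTS / "probe_segments.tsv",
    )
    print(f"wrote {RESULTS / 'probe_hydropathy.tsv'}")


if __name__ == "__main__":
    main()
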