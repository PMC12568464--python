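"""Cross-check published closed-form index expressions against partition sums.

Every closed-form index expression of the two families is re-derived
exactly from the edge-partition model and compared with the published
polynomial/radical form at n = 1..10.  For the kekulene family all eight
non-parametric forms agree.  For the Sierpinski family the published
harmonic-index expression is flagged: its constant term reads 72 where the
partition sum gives 7/2, so it evaluates to 151.1 instead of 82.6 at n=1 —
a known misprint; the partition sums are authoritative.
"""

from topoentropy import verify_closed_forms

for family in ("KE", "SE"):
    report = verify_closed_forms(family, range(1, 11))
    print(report.to_text())
    print()
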