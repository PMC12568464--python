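"""Entropy tables for the two fractal families.

Evaluates the symbolic edge-partition models of the kekulene fractal (KE)
and the terpyridine Sierpinski triangle (SE) at growth stages n = 1..10
and prints the ten-descriptor entropy table of each family, rounded to
4 decimals.  Entropies grow with n because the edge count grows (the
ceiling is log |E|); for KE the growth becomes linear with slope log 12,
the growth factor of its dominant (3,3) edge class.
"""

from topoentropy import reference_entropy_table

for family in ("KE", "SE"):
    frame = reference_entropy_table(family, n_max=10)
    print(f"\n{family} family, index entropies in nats (rows: growth stage n):")
    print(frame.round(4).to_string())
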