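"""Unique-mappability of repeated sequence at different divergences.

Young L1 subfamilies are nearly identical copy to copy, so short reads
cannot be placed uniquely; older subfamilies have accumulated diagnostic
substitutions.  This demo duplicates a sequence at several divergences and
measures the fraction of positions a 100-bp read can be uniquely mapped to.
"""

import numpy as np

from l1locus.mappability import compute_mappability, interval_mappability

rng = np.random.default_rng(1)
bases = np.frombuffer(b"ACGT", dtype=np.uint8)
rand = lambda n: bases[rng.integers(0, 4, n)].tobytes().decode()


def mutate(seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + 1) % 4]
    return "".join(out)


core = rand(4000)
print("divergence   mappable fraction of the first copy (L=100)")
for rate in (0.0, 0.005, 0.01, 0.02, 0.05):
    genome = {"chr": rand(1000) + core + mutate(core, rate) + rand(1000)}
    track = compute_mappability(genome, read_length=100)
    frac = interval_mappability(track, "chr", 1000, 5000)
    print(f"  {rate:5.1%}      {frac:.3f}")

print("\nIdentical copies (0%) are invisible to unique mapping; by ~5%")
print("divergence almost every 100-mer contains a diagnostic base and the")
print("copy becomes fully mappable.  This is why locus-specific L1 calls")
print("undercount the youngest, most retrotransposition-competent elements.")
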