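"""Scan a sequence with a toy CTCF-like PWM and annotate peak orientation.

CTCF motif orientation constrains loop formation: two motifs pointing apart
(reverse upstream of forward) are "divergent", the opposite "convergent".
A peak carrying the motif on one strand takes that orientation.
"""

import numpy as np

from domainscope.core import GenomicRegion
from domainscope.motifs import PFM, annotate_peak_orientation, pfm_to_pwm, scan_sequence

# strongly-informative toy motif, consensus ACGTA
counts = np.zeros((4, 5))
for k, base in enumerate("ACGTA"):
    counts["ACGT".index(base), k] = 10.0
pfm = PFM(counts, name="toy-ctcf")
pwm = pfm_to_pwm(pfm)

rng = np.random.default_rng(0)
filler = lambda n: "".join(rng.choice(list("ACGT"), n))
# reverse-complement motif at 20, forward motif at 60 -> divergent pair
seq = filler(20) + "TACGT" + filler(35) + "ACGTA" + filler(20)
hits = scan_sequence(seq, pwm, threshold=0.95)
for h in hits:
    print(f"hit at {h.position:3d} strand {h.strand} score {h.score:.2f}")

peaks = [GenomicRegion("chr14", 0, len(seq))]
print("peak orientation:", annotate_peak_orientation(peaks, hits)[0])
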