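"""Collapse redundant end-reads into contigs by greedy overlap clustering.

Fragments a 3-kb template into overlapping pieces (some reverse-
complemented), adds two unrelated reads, and clusters at the survey's
thresholds: minimum 80 bp overlap at 95% identity. The fragments
reassemble into one contig; the unrelated reads stay singletons.
"""

import numpy as np

from beskit._util import revcomp
from beskit.io_formats import SequenceRecord
from beskit.redundancy_assembly import greedy_assemble

rng = np.random.default_rng(11)
bases = np.array(list("ACGT"))
rand = lambda n: "".join(rng.choice(bases, n))

template = rand(3_000)
reads = []
pos = 0
for i in range(6):
    frag = template[pos:pos + 700]
    if i % 2:
        frag = revcomp(frag)
    reads.append(SequenceRecord(f"read{i}", frag))
    pos += 500  # 200 bp overlap between neighbours
reads += [SequenceRecord("lone1", rand(600)), SequenceRecord("lone2", rand(600))]

asm = greedy_assemble(reads, min_overlap=80, min_identity=95.0)
print(f"{len(reads)} reads -> {len(asm.contigs)} contig(s), "
      f"{len(asm.singletons)} singleton(s)")
for consensus, members in asm.contigs:
    print(f"  {consensus.id}: {len(consensus.sequence)} bp from {sorted(members)}")
# the contig consensus spans the template region covered by its members;
# reads without an accepted overlap against any cluster stay singletons.
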