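"""Post-process a case-encoded corrected read.

Corrected reads mark solid bases upper case and weak bases lower case.
``trim`` drops weak ends only; ``trim_split`` extracts each solid run.
"""

from hybridec import CorrectedRead, trim, trim_split

read = CorrectedRead(name="example", seq="acgGGTACCGTtacgACCGGT" + "gt")
print(f"input:      {read.seq}")

trimmed = trim(read)
print(f"trimmed:    {trimmed.seq}   (weak ends removed, inner weak kept)")

for name, piece in trim_split(read):
    print(f"split:      {name} = {piece}")
# Each split piece is a maximal stretch of bases confirmed by the short-read
# graph, usable where downstream tools require fully validated sequence.
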