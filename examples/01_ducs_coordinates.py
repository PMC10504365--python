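"""The DucS worked example: published coordinates -> transcript/circle sizes.

DucS is a bacterial sRNA with one TSS, two termination sites and two
circularization junction families (S1 at the TSS, S2 at 26-35 nt
downstream), all sharing a fixed 3' terminus one base past the first TTS.
Inclusive coordinate arithmetic alone reproduces every published size:
linear forms of 232 and 199 nt, circles of 200 and 165-174 nt.
"""

from circbact import ducs_fixture

fixture = ducs_fixture()
print(fixture.table().to_string(index=False))
print()
print(
    f"fixed circle 3' terminus: position {fixture.donor_3p} "
    f"(one base past TTS_1st at {fixture.boundary.tts_list[0]})"
)
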