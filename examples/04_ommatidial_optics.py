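"""Ommatidial optics of the two study species.

White-light optical sensitivity S from the acute-zone morphology, plus
the two angular figures that bound the acceptance angle: the Airy-disk
half-width lambda/D and the rhabdom subtense d/f.
"""

from waspeye import optics_table

table = optics_table()
cols = ["label", "D_um", "d_um", "l_um", "S_um2_sr",
        "airy_halfwidth_deg", "rhabdom_subtense_deg"]
print(table[cols].round(3).to_string(index=False))
print()
print("S combines aperture (D^2), image-node geometry ((d/f)^2) and")
print("rhabdom absorption kl/(2.3+kl); both values are typical of")
print("day-active hymenopterans with apposition eyes.")
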