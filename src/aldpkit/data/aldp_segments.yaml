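# Curated default segment annotation for human ALDP/ABCD1 (UniProt P33897,
# 745 aa), author numbering, both chains of the homodimer.
#
# EH (364-374) and CH (683-745) are pinned by the published deletion
# constructs. TM1-TM6 and NBD bounds are curated approximations from
# ABC transporter domain organisation, NOT deposited-entry annotations;
# recalibrate against the coordinates of a deposited model before using
# these for quantitative claims on real structures.
TM1: [[A, 92, 120], [B, 92, 120]]
TM2: [[A, 131, 160], [B, 131, 160]]
TM3: [[A, 236, 258], [B, 236, 258]]
TM4: [[A, 330, 360], [B, 330, 360]]
TM5: [[A, 380, 410], [B, 380, 410]]
TM6: [[A, 430, 465], [B, 430, 465]]
EH: [[A, 364, 374], [B, 364, 374]]
CH: [[A, 683, 745], [B, 683, 745]]
NBD: [[A, 487, 682], [B, 487, 682]]
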