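"""Overlap channels: why six orthogonal attP/attB pairs exist.

The 2 bp central overlap of an att site must match between recombining
sites, and reverse-complement overlaps describe the same duplex read from
the other strand. Grouping the 16 dinucleotides this way gives 6 asymmetric
channels (usable for ordered assembly) and 4 symmetric ones (which
recombine in both orientations).
"""

from sira import AttSite, INT_ONLY, channel_of, enumerate_channels, sites_compatible

channels = enumerate_channels()
asym = [c for c in channels if not c.symmetric]
sym = [c for c in channels if c.symmetric]
print(f"{len(channels)} channels over 16 dinucleotides: "
      f"{len(asym)} asymmetric + {len(sym)} symmetric")
print("asymmetric (orthogonal, orientation-enforcing):",
      ", ".join(c.name for c in asym))
print("symmetric (recombine both ways):", ", ".join(c.name for c in sym))

p_tt = AttSite.make("P", "TT")
print("\nattP^TT vs attB^TT  ->",
      sites_compatible(p_tt, AttSite.make("B", "TT"), INT_ONLY))
print("attP^TT vs attB^TC  ->",
      sites_compatible(p_tt, AttSite.make("B", "TC"), INT_ONLY))
print("attP^TT vs reversed attB^AA ->",
      sites_compatible(p_tt, AttSite.make("B", "AA", "reverse"), INT_ONLY))
print("\nTT and AA name the same channel:",
      channel_of("TT") == channel_of("AA"))
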