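# Synthetic REL4536-like replication geometry.
#
# The replichore arc lengths match the published values for E. coli REL4536
# (clockwise 2.06 Mb, counter-clockwise 2.54 Mb; the asymmetry stems from a
# large IS1-mediated inversion relative to REL606).  The origin is placed at
# coordinate 1 for convenience and the six macrodomain intervals are
# synthetic placeholders tiling the 4.6 Mb circle in the canonical order
# (Ori, NS-right, Right, Ter, Left, NS-left), with the Ter macrodomain
# containing the replication terminus.  Exact strain coordinates are not
# published; override this file for a genuinely annotated genome.
ori: 1
ter: 2060001
macrodomains:
  - {name: Ori,      start: 1,       end: 500001}
  - {name: NS-right, start: 500001,  end: 1100001}
  - {name: Right,    start: 1100001, end: 1600001}
  - {name: Ter,      start: 1600001, end: 2600001}
  - {name: Left,     start: 2600001, end: 3600001}
  - {name: NS-left,  start: 3600001, end: 4600001}
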