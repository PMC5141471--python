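# Default archaeological period grid, years before present (BP, 1950 datum),
# oldest first.  The nine-period layout follows the usual central-European
# periodisation; exact boundaries are editable because published sources only
# pin the coarse ones (pre-domestic >4000 BC, early domestic 4000-2700 BC,
# Bronze 2700-900 BC, Iron 900 BC-400 AD, Medieval 400-1500 AD).
periods:
  - {name: Pleistocene,         start: 126000, end: 11700}
  - {name: MesolithicNeolithic, start: 11700,  end: 5950}
  - {name: CopperAge,           start: 5950,   end: 4650}
  - {name: EarlyBronzeAge,      start: 4650,   end: 3950}
  - {name: MiddleBronzeAge,     start: 3950,   end: 3350}
  - {name: LateBronzeAge,       start: 3350,   end: 2850}
  - {name: EarlyIronAge,        start: 2850,   end: 2450}
  - {name: IronAge,             start: 2450,   end: 1550}
  - {name: Medieval,            start: 1550,   end: 450}
# Optional split of the Middle Ages used when contrasting early vs late:
medieval_split:
  - {name: EarlyMedieval, start: 1550, end: 950}
  - {name: LateMedieval,  start: 950,  end: 450}
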