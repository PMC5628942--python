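# Historical per-event boolean filtering rules (one rule line per entry;
# a message is included if any line for its event matches).
SH:
  - "School (gunman OR 'Sandy Hook' OR victims OR shooting OR Newtown)"
  - "Newtown (shooting OR gunman OR student OR Sandy Hook OR elementary)"
BB:
  - "Bomb (Boston OR marathon OR explosion OR terrorist OR finish line)"
  - "Boston (explosion OR terrorist)"
SF:
  - "Plane (crash OR SFO OR runway OR San Francisco OR Asiana OR '214')"
  - "Asiana (Crash OR '214' OR Runway OR SFO OR San Francisco)"
NE:
  - "Earthquake (San Francisco OR 'sf' OR Napa OR '6.0')"
MV:
  - "School (gunman OR Marysville OR victims OR shooting OR Washington)"
  - "Marysville (shooting OR gunman OR student)"
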