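# Joint event+location keyword sets for prospective matching: a message
# must contain at least one word from each list.
event:
  - breaking
  - news
  - breakingnews
  - cnn
  - pray
  - crash
  - shot
  - shooting
  - stab
  - stabbed
  - stabbing
  - fall
  - dead
  - died
  - accident
  - earthquake
  - flood
  - victim
  - victims
  - fatality
  - fatalities
  - attack
location:
  - sf
  - sanfrancisco
  - san
  - francisco
  - sanfran
  - prayforsanfrancisco
  - bayarea
  - sfbayarea
  - bay
  - sanfranciscobay
  - northerncalifornia
  - norcal
  - california
  - ca
  - sfgh
  - zfgh
  - thegeneral
  - general
  - goldengatebridge
  - goldengate
  - bridge
  - baybridge
  - bart
  - caltrain
  - muni
  - cablecar
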