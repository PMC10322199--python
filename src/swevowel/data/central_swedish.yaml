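# Default vowel inventory: the 22 hVd / hVdd words covering the Central
# Swedish monophthong space (9 long vowels, 9 short vowels, 4 contextually
# conditioned allophones before /r/ or retroflexes).  The value is the
# quantity class of each category.  "hädd" elicits the same short vowel as
# "hedd" and is conventionally dropped from analyses (see
# data_model.apply_exclusions); it is listed here because it occurs in raw
# recordings.  Users may supply their own inventory file in this format.
hid: long      # [i:]
hyd: long      # [y:]
hud: long      # [ʉ:]
hed: long      # [e:]
häd: long      # [ε:]
höd: long      # [ø:]
had: long      # [ɑ:]
håd: long      # [o:]
hod: long      # [u:]
härd: long     # [æ:], allophone of /ε:/ before retroflex
hörd: long     # [œ:], allophone of /ø:/ before retroflex
hidd: short    # [ɪ]
hydd: short    # [ʏ]
hudd: short    # [ɵ]
hedd: short    # [ε]
hädd: short    # [ε] (same vowel as hedd; dropped by default exclusions)
hödd: short    # [œ]
hadd: short    # [a]
hådd: short    # [ɔ]
hodd: short    # [ʊ]
härr: short    # [æ], allophone before /r/
hörr: short    # [œ], allophone before /r/
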