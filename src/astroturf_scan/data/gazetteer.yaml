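# Location keyword lists for free-text profile locations.
# Matching is whole-word, case-insensitive, longest keyword first, with
# precedence chicago_area > illinois > us_states > countries.  Two-letter
# state abbreviations that collide with common English words (IN, OR, ME,
# OK, HI, DE, OH, AL) are deliberately omitted.
chicago_area:
  - chicago
  - chicagoland
  - windy city
  - evanston
  - oak park
  - skokie
  - naperville
  - cicero
  - berwyn
  - schaumburg
  - des plaines
  - elgin
  - joliet
  - waukegan
  - aurora
illinois:
  - illinois
  - il
  - springfield
  - peoria
  - rockford
  - champaign
  - urbana
  - bloomington
  - decatur
  - carbondale
us_states:
  - usa
  - u.s.a.
  - u.s.
  - united states
  - america
  - alabama
  - alaska
  - arizona
  - arkansas
  - california
  - colorado
  - connecticut
  - delaware
  - florida
  - georgia
  - hawaii
  - idaho
  - indiana
  - iowa
  - kansas
  - kentucky
  - louisiana
  - maine
  - maryland
  - massachusetts
  - michigan
  - minnesota
  - mississippi
  - missouri
  - montana
  - nebraska
  - nevada
  - new hampshire
  - new jersey
  - new mexico
  - new york
  - north carolina
  - north dakota
  - ohio
  - oklahoma
  - oregon
  - pennsylvania
  - rhode island
  - south carolina
  - south dakota
  - tennessee
  - texas
  - utah
  - vermont
  - virginia
  - washington
  - west virginia
  - wisconsin
  - wyoming
  - ak
  - az
  - ar
  - ca
  - co
  - ct
  - fl
  - ga
  - ia
  - ks
  - ky
  - la
  - md
  - ma
  - mi
  - mn
  - ms
  - mo
  - mt
  - ne
  - nv
  - nh
  - nj
  - nm
  - ny
  - nc
  - nd
  - pa
  - ri
  - sc
  - sd
  - tn
  - tx
  - ut
  - vt
  - va
  - wa
  - wv
  - wi
  - wy
  - nyc
  - new york city
  - los angeles
  - brooklyn
  - denver
  - austin
  - seattle
  - portland
  - phoenix
  - atlanta
  - tampa
  - boston
  - houston
  - dallas
  - miami
  - philadelphia
  - san francisco
  - san diego
  - las vegas
  - nashville
  - minneapolis
  - detroit
  - cleveland
  - pittsburgh
  - baltimore
countries:
  - canada
  - united kingdom
  - uk
  - u.k.
  - england
  - scotland
  - wales
  - ireland
  - france
  - germany
  - spain
  - italy
  - portugal
  - netherlands
  - belgium
  - switzerland
  - austria
  - sweden
  - norway
  - denmark
  - finland
  - poland
  - greece
  - russia
  - australia
  - new zealand
  - japan
  - china
  - india
  - brazil
  - mexico
  - argentina
  - south africa
  - london
  - manchester
  - glasgow
  - dublin
  - toronto
  - vancouver
  - montreal
  - sydney
  - melbourne
  - athens
  - paris
  - berlin
  - amsterdam
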