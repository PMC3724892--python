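species:
- id: DHK
  role: intermediate
  display_name: dihydrokaempferol
- id: DHQ
  role: intermediate
  display_name: dihydroquercetin
- id: DHM
  role: intermediate
  display_name: dihydromyricetin
- id: KMP
  role: intermediate
  display_name: kaempferol aglycone
- id: QUE
  role: intermediate
  display_name: quercetin aglycone
- id: MYR
  role: intermediate
  display_name: myricetin aglycone
- id: LCD
  role: intermediate
  display_name: leucodelphinidin
- id: DPH
  role: intermediate
  display_name: delphinidin aglycone
- id: KMPg
  role: end_product
  display_name: kaempferol glycosides
- id: QUEg
  role: end_product
  display_name: quercetin glycosides
- id: MYRg
  role: end_product
  display_name: myricetin glycosides
- id: ANT
  role: end_product
  display_name: anthocyanins (delphinidin derivatives)
reactions:
- id: F3H:->DHK
  kind: influx
  target: DHK
  enzyme: F3H
- id: F3'H:DHK->DHQ
  kind: conversion
  source: DHK
  target: DHQ
  enzyme: F3'H
- id: F3'H:KMP->QUE
  kind: conversion
  source: KMP
  target: QUE
  enzyme: F3'H
- id: F3'5'H:DHK->DHQ
  kind: conversion
  source: DHK
  target: DHQ
  enzyme: F3'5'H
- id: F3'5'H:DHK->DHM
  kind: conversion
  source: DHK
  target: DHM
  enzyme: F3'5'H
- id: F3'5'H:DHQ->DHM
  kind: conversion
  source: DHQ
  target: DHM
  enzyme: F3'5'H
- id: F3'5'H:KMP->QUE
  kind: conversion
  source: KMP
  target: QUE
  enzyme: F3'5'H
- id: F3'5'H:KMP->MYR
  kind: conversion
  source: KMP
  target: MYR
  enzyme: F3'5'H
- id: F3'5'H:QUE->MYR
  kind: conversion
  source: QUE
  target: MYR
  enzyme: F3'5'H
- id: FLS:DHK->KMP
  kind: conversion
  source: DHK
  target: KMP
  enzyme: FLS
- id: FLS:DHQ->QUE
  kind: conversion
  source: DHQ
  target: QUE
  enzyme: FLS
- id: FLS:DHM->MYR
  kind: conversion
  source: DHM
  target: MYR
  enzyme: FLS
- id: DFR:DHM->LCD
  kind: conversion
  source: DHM
  target: LCD
  enzyme: DFR
- id: ANS:LCD->DPH
  kind: conversion
  source: LCD
  target: DPH
  enzyme: ANS
- id: GT:KMP->KMPg
  kind: conversion
  source: KMP
  target: KMPg
  enzyme: GT
- id: GT:QUE->QUEg
  kind: conversion
  source: QUE
  target: QUEg
  enzyme: GT
- id: GT:MYR->MYRg
  kind: conversion
  source: MYR
  target: MYRg
  enzyme: GT
- id: GT:DPH->ANT
  kind: conversion
  source: DPH
  target: ANT
  enzyme: GT
- id: red:KMPg
  kind: reduction
  source: KMPg
- id: red:QUEg
  kind: reduction
  source: QUEg
- id: red:MYRg
  kind: reduction
  source: MYRg
- id: red:ANT
  kind: reduction
  source: ANT
enzymes:
- F3H
- F3'H
- F3'5'H
- FLS
- DFR
- ANS
- GT
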