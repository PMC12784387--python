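{
  "version": 1,
  "rules": [
    {
      "material": "colophony",
      "required": [
        [
          "class:resin_acid_abietane"
        ]
      ],
      "weights": {
        "component:abietic acid": 1.0,
        "component:dehydroabietic acid": 1.0,
        "component:didehydroabietic acid": 1.0,
        "component:7-oxodehydroabietic acid": 1.0,
        "component:15-hydroxydehydroabietic acid": 1.0,
        "component:15-hydroxy-7-oxodehydroabietic acid": 1.0,
        "combo:resin_dimer": 2.0
      }
    },
    {
      "material": "pine_tar",
      "required": [
        [
          "component:retene"
        ],
        [
          "component:simonellite"
        ]
      ],
      "weights": {
        "component:retene": 2.0,
        "component:simonellite": 2.0,
        "class:resin_acid_abietane": 1.0
      }
    },
    {
      "material": "drying_oil",
      "required": [
        [
          "combo:diacid_glycerolipid",
          "class:dicarboxylic_acid"
        ]
      ],
      "weights": {
        "combo:diacid_glycerolipid": 2.0,
        "class:dicarboxylic_acid": 1.0,
        "class:degradation_acid": 1.0,
        "combo:glycerolipid": 1.0
      }
    },
    {
      "material": "egg_yolk",
      "required": [
        [
          "component:cholesterol",
          "component:3-hydroxycholest-5-en-7-one"
        ]
      ],
      "weights": {
        "component:cholesterol": 2.0,
        "component:3-hydroxycholest-5-en-7-one": 1.0,
        "combo:glycerolipid": 1.0
      }
    },
    {
      "material": "dammar",
      "required": [
        [
          "class:triterpenoid_dammarane",
          "class:triterpenoid_pentacyclic"
        ],
        [
          "combo:dammarane+cadinene"
        ]
      ],
      "weights": {
        "component:dammaradienol": 0.5,
        "component:dammaradienone": 0.5,
        "component:hydroxydammarenone": 0.5,
        "component:dammarenolic acid": 0.5,
        "component:oleanonic/ursonic acid": 0.5,
        "component:nor-amyrone": 0.5,
        "combo:dammarane+cadinene": 2.0
      }
    },
    {
      "material": "beeswax",
      "required": [
        [
          "combo:wax_ester"
        ]
      ],
      "weights": {
        "combo:wax_ester": 2.0,
        "class:wax_alkane": 1.0,
        "class:wax_alcohol": 0.5,
        "class:wax_diol": 0.5
      }
    }
  ]
}
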