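{
  "chain_id": "A",
  "cutoff_A": 5.0,
  "ligand_code": "ABL",
  "positions": [
    {
      "number": 278,
      "provenance": "distance"
    },
    {
      "number": 279,
      "provenance": "distance"
    },
    {
      "number": 282,
      "provenance": "distance"
    },
    {
      "number": 297,
      "provenance": "distance"
    },
    {
      "number": 310,
      "provenance": "distance"
    },
    {
      "number": 312,
      "provenance": "distance"
    },
    {
      "number": 562,
      "provenance": "distance"
    },
    {
      "number": 563,
      "provenance": "distance"
    },
    {
      "number": 584,
      "provenance": "distance"
    },
    {
      "number": 586,
      "provenance": "distance"
    },
    {
      "number": 590,
      "provenance": "distance"
    },
    {
      "number": 607,
      "provenance": "distance"
    },
    {
      "number": 609,
      "provenance": "distance"
    },
    {
      "number": 686,
      "provenance": "distance"
    },
    {
      "number": 687,
      "provenance": "distance"
    },
    {
      "number": 688,
      "provenance": "distance"
    },
    {
      "number": 689,
      "provenance": "distance"
    },
    {
      "number": 732,
      "provenance": "distance"
    },
    {
      "number": 733,
      "provenance": "distance"
    }
  ],
  "structure_id": "1NAA"
}
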