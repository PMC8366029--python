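{
  "chain_id": "A",
  "cutoff_A": 5.0,
  "ligand_code": "UNK",
  "positions": [
    {
      "number": 38,
      "provenance": "literature"
    },
    {
      "number": 39,
      "provenance": "literature"
    },
    {
      "number": 40,
      "provenance": "literature"
    },
    {
      "number": 63,
      "provenance": "literature"
    },
    {
      "number": 66,
      "provenance": "literature"
    },
    {
      "number": 67,
      "provenance": "literature"
    },
    {
      "number": 78,
      "provenance": "literature"
    },
    {
      "number": 114,
      "provenance": "literature"
    },
    {
      "number": 115,
      "provenance": "literature"
    },
    {
      "number": 116,
      "provenance": "literature"
    },
    {
      "number": 117,
      "provenance": "literature"
    },
    {
      "number": 118,
      "provenance": "literature"
    },
    {
      "number": 137,
      "provenance": "literature"
    },
    {
      "number": 149,
      "provenance": "literature"
    },
    {
      "number": 262,
      "provenance": "literature"
    },
    {
      "number": 288,
      "provenance": "literature"
    },
    {
      "number": 291,
      "provenance": "literature"
    },
    {
      "number": 292,
      "provenance": "literature"
    },
    {
      "number": 295,
      "provenance": "literature"
    },
    {
      "number": 296,
      "provenance": "literature"
    }
  ],
  "structure_id": "1C1D"
}
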