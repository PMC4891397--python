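{
  "floor_height": 4.0,
  "start": "A",
  "rooms": [
    {
      "id": "A",
      "name": "corridor A",
      "floor": 0,
      "block": null,
      "x": 0.0,
      "y": 0.0,
      "category": "corridor"
    },
    {
      "id": "B",
      "name": "corridor B",
      "floor": 0,
      "block": null,
      "x": 6.0,
      "y": 0.0,
      "category": "corridor"
    },
    {
      "id": "C",
      "name": "room C",
      "floor": 0,
      "block": null,
      "x": 12.0,
      "y": 4.0,
      "category": "room"
    },
    {
      "id": "D",
      "name": "room D",
      "floor": 0,
      "block": null,
      "x": 12.0,
      "y": 0.0,
      "category": "room"
    },
    {
      "id": "E",
      "name": "room E",
      "floor": 0,
      "block": null,
      "x": 12.0,
      "y": -4.0,
      "category": "room"
    }
  ],
  "edges": [
    {
      "source": "A",
      "target": "B",
      "link_type": "corridor"
    },
    {
      "source": "B",
      "target": "C",
      "link_type": "door"
    },
    {
      "source": "B",
      "target": "D",
      "link_type": "door"
    },
    {
      "source": "B",
      "target": "E",
      "link_type": "door"
    }
  ]
}
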