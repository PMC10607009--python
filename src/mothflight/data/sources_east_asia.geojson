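{
 "type": "FeatureCollection",
 "features": [
  {
   "type": "Feature",
   "properties": {
    "name": "Zhejiang"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       118.0,
       28.2
      ],
      [
       118.4,
       29.4
      ],
      [
       119.3,
       30.6
      ],
      [
       120.2,
       31.0
      ],
      [
       121.3,
       30.9
      ],
      [
       122.2,
       30.2
      ],
      [
       121.9,
       29.2
      ],
      [
       121.2,
       28.2
      ],
      [
       120.3,
       27.5
      ],
      [
       119.0,
       27.3
      ],
      [
       118.4,
       27.8
      ],
      [
       118.0,
       28.2
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "Fujian"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       115.9,
       25.0
      ],
      [
       116.5,
       24.2
      ],
      [
       117.3,
       23.6
      ],
      [
       118.2,
       24.3
      ],
      [
       119.0,
       25.0
      ],
      [
       119.8,
       25.8
      ],
      [
       120.2,
       26.6
      ],
      [
       120.3,
       27.2
      ],
      [
       119.6,
       27.9
      ],
      [
       118.6,
       28.2
      ],
      [
       117.8,
       27.8
      ],
      [
       117.0,
       27.1
      ],
      [
       116.3,
       26.2
      ],
      [
       115.9,
       25.0
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "Guangdong"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       109.9,
       21.3
      ],
      [
       111.0,
       21.4
      ],
      [
       112.4,
       21.7
      ],
      [
       113.4,
       22.1
      ],
      [
       114.6,
       22.5
      ],
      [
       115.8,
       22.7
      ],
      [
       116.8,
       23.2
      ],
      [
       117.2,
       23.7
      ],
      [
       116.5,
       24.6
      ],
      [
       115.5,
       25.0
      ],
      [
       114.2,
       25.4
      ],
      [
       112.8,
       25.2
      ],
      [
       111.5,
       24.7
      ],
      [
       110.5,
       24.1
      ],
      [
       109.9,
       22.8
      ],
      [
       109.9,
       21.3
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "Jiangxi"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       113.9,
       25.3
      ],
      [
       115.0,
       24.7
      ],
      [
       116.0,
       25.3
      ],
      [
       116.6,
       26.0
      ],
      [
       117.3,
       27.0
      ],
      [
       118.1,
       27.9
      ],
      [
       118.3,
       28.5
      ],
      [
       117.7,
       29.5
      ],
      [
       116.8,
       30.0
      ],
      [
       115.8,
       29.9
      ],
      [
       114.9,
       29.6
      ],
      [
       114.2,
       28.8
      ],
      [
       113.8,
       27.5
      ],
      [
       113.7,
       26.3
      ],
      [
       113.9,
       25.3
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "Taiwan"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       120.2,
       22.7
      ],
      [
       120.6,
       22.0
      ],
      [
       120.9,
       21.9
      ],
      [
       121.3,
       22.6
      ],
      [
       121.6,
       23.5
      ],
      [
       121.9,
       24.5
      ],
      [
       121.9,
       25.0
      ],
      [
       121.4,
       25.3
      ],
      [
       120.8,
       25.1
      ],
      [
       120.3,
       24.2
      ],
      [
       120.1,
       23.5
      ],
      [
       120.2,
       22.7
      ]
     ]
    ]
   }
  }
 ]
}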