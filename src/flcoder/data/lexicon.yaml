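# Default multi-language keyword lexicon for food-facility classification.
#
# This list is a reconstruction for the Spanish/Catalan urban context: the
# original tool's keyword list was never published, so these entries were
# assembled from common storefront vocabulary and OpenStreetMap tagging
# practice.  Edit freely: categories match on either source tags
# (key=value pairs from the place metadata) or whole-token keyword phrases
# found in the normalized facility name.
precedence: [fast_food, supermarket, bar_restaurant, convenience_other]
categories:
  fast_food:
    tags:
      - amenity=fast_food
      - cuisine=burger
      - cuisine=kebab
      - cuisine=pizza
      - cuisine=fried_chicken
    keywords:
      es:
        - kebab
        - hamburgueseria
        - pizzeria
        - comida rapida
        - pollo frito
        - shawarma
        - bocadillos
      ca:
        - frankfurt
        - entrepans
        - pizzes
      en:
        - fast food
        - burger
        - pizza
        - fried chicken
        - takeaway
        - mcdonalds
        - kfc
        - burger king
        - telepizza
        - dominos
  supermarket:
    tags:
      - shop=supermarket
      - shop=hypermarket
      - shop=wholesale
    keywords:
      es:
        - supermercado
        - hipermercado
        - autoservicio
        - mercadona
        - carrefour
        - lidl
        - aldi
        - eroski
        - consum
        - dia
      ca:
        - supermercat
        - hipermercat
        - caprabo
        - bonpreu
        - esclat
        - sorli
      en:
        - supermarket
        - hypermarket
        - grocery store
  bar_restaurant:
    tags:
      - amenity=bar
      - amenity=restaurant
      - amenity=cafe
      - amenity=pub
      - amenity=biergarten
    keywords:
      es:
        - bar
        - restaurante
        - cafeteria
        - taberna
        - meson
        - bodega
        - cerveceria
        - marisqueria
        - asador
        - chiringuito
        - tapas
      ca:
        - restaurant
        - cerveseria
        - taverna
        - celler
        - braseria
        - granja
      en:
        - cafe
        - bistro
        - pub
        - coffee
        - brasserie
  convenience_other:
    tags:
      - shop=convenience
      - shop=bakery
      - shop=butcher
      - shop=greengrocer
      - shop=seafood
      - shop=confectionery
      - shop=pastry
      - shop=frozen_food
      - shop=deli
      - shop=kiosk
      - amenity=marketplace
      - amenity=ice_cream
    keywords:
      es:
        - panaderia
        - pasteleria
        - carniceria
        - pescaderia
        - fruteria
        - charcuteria
        - ultramarinos
        - alimentacion
        - colmado
        - golosinas
        - heladeria
        - congelados
        - kiosco
        - estanco
      ca:
        - forn
        - forn de pa
        - pastisseria
        - carnisseria
        - peixateria
        - fruiteria
        - xarcuteria
        - queviures
        - gelateria
        - llaminadures
        - mercat
      en:
        - bakery
        - butcher
        - greengrocer
        - convenience
        - minimarket
        - mini market
        - ice cream
        - candy
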