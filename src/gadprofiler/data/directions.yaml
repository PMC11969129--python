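# A-priori one-tailed test directions, declared per feature before any data
# are seen ("greater" = diagnosed group mean above control).  Content features
# follow the hypothesis that anxiety-related language and themes are elevated
# in the diagnosed group; behavioral directions encode the hypothesized
# withdrawal pattern (less outward engagement, more reactive replying).
linguistic:
  insight: greater
  causation: greater
  discrepancy: greater
  tentativeness: greater
  certitude: greater
  differentiation: greater
  memory: greater
  need: greater
  want: greater
  lack: greater
  reward: less
  risk: greater
  curiosity: greater
  substances: greater
  food: greater
  death: greater
  interpersonal_conflict: greater
  communication: less
  negative_tone: greater
  anxiety: greater
  anger: greater
  sadness: greater
  swear_words: greater
theme:
  symptoms: greater
  life_problems: greater
  relationships: greater
  feelings: greater
  per_tweet_freq: greater
volume:
  follower_count: less
  friend_count: less
  listed_count: less
  favorite_count: less
  status_count: less
  retweets_received_total: less
  n_tweets: less
  n_replies: greater
  n_hashtag_tweets: less
  n_retweets: less
  n_mentions_total: less
  n_mentions_excl_replies: less
  n_tweets_with_retweets: less
  n_tweets_with_favorites: less
behavior:
  ff_ratio: greater
  reply_to_tweet_ratio: greater
  hashtag_ratio: less
  retweet_to_tweet_ratio: less
  mention_ratio: less
  mentions_per_tweet: less
  tweets_with_retweets_ratio: less
  tweets_with_favorites_ratio: less
  tweets_per_day: less
  replies_per_day: greater
  retweets_per_day: less
  mentions_per_day: less
  hashtag_tweets_per_day: less
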